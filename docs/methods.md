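# Methods

## The estimation problem

A germination assay places 30–60 seeds of one rice variety in a petri
dish; after a fixed incubation time an overhead photograph (nominally
1920×1080, controlled lighting, dark dish background) is scored for the
fraction of seeds with a protruding radicle. `seedgerm` estimates that
fraction from the image alone. The pipeline assumes: yellowish seed coats
(R and G well above B), a dark background and a near-white radicle (all
channels balanced), seeds that may touch but mostly lie separate, and
impurities (awns, stalk fragments, droplet highlights) that are small
relative to a seed.

## Segmentation

Smoothing uses a sampled-Gaussian 3×3 kernel. The kernel size is part of
the method; σ is not, and we fix σ = 0.8 — the usual choice for a
single-pixel-radius kernel — normalized to unit sum, with edge replication
at borders and round-half-up back to 8-bit.

The feature transform f₁ = R − B, f₂ = G − B is applied to the smoothed
image, kept signed and unclamped. Two-cluster Lloyd k-means starts from
centers (0, 0) and (30, 30). Numerical choices:

- convergence when both centers move < 10⁻³ (Euclidean), hard cap 100
  iterations — the feature lattice is integer-valued, so this is
  effectively exact;
- assignment ties go to the cluster initialized at (30, 30), which makes
  the coat/background orientation deterministic on symmetric inputs;
- an emptied cluster keeps its previous center and flags the result
  degenerate, as does an input with a single distinct feature value;
- iteration runs on the unique feature values weighted by multiplicity,
  which is algebraically identical to per-pixel Lloyd but ~50× faster on
  full-HD frames (the lattice holds at most 511² distinct points). An
  optional stride subsample is available for even larger frames; the final
  assignment always covers every pixel.

The coat cluster is the one whose converged center has the larger
coordinate sum.

## Counting

Coat components are extracted at 8-connectivity by default (seeds are
blob-like and diagonal contact is common; 4-connectivity is a config
switch) and components under 200 px are dropped as noise. The single-seed
area s_opt is the mean of the "stable prefix" of the ascending area curve:
the components covered by the initial run of at least two consecutive gaps
Δᵢ < 30 px, ending at the first gap ≥ 30 px. If no such run starts the
curve (or fewer than three components survive), s_opt falls back to the
median of all areas and the estimate is flagged low-confidence — counting
still proceeds, only the provenance of s_opt changes.

The total N_s = Σ ⌊sᵢ/s_opt⌋ is the default (floor) rule, summed over all
surviving components. The floor can assign multiplicity 0 to a component a
few pixels under s_opt, undercounting single seeds; a `rounded` mode
max(1, round(sᵢ/s_opt)) avoids that and is what the synthetic recovery
suites use. Both rules are exposed; floor stays the default for fidelity
to the method as published.

## Germination standards

Radicle candidates are non-coat pixels with all channels strictly above
160. "Extremely small or large" candidate regions are removed with bounds
we had to quantify ourselves: min 20 px (drops droplet highlights and
glint), max 5·s_opt (drops rim reflections and merged glare), both
configurable. The area standard counts regions with area **strictly
greater** than T_g (default 100 px); the ratio standard compares a seed's
radicle-to-seed area ratio **inclusively** against the reference ratio r₀.
The asymmetry (strict vs inclusive) mirrors how each rule is stated in the
field's practice, and keeping it means the reference seed itself always
classifies as germinated.

Two ratio conventions coexist: radicle/seed-body (`ratio_body`, used with
the fixed 0.4 standard) and radicle/whole-seed (`ratio_whole`, used by the
reference-seed classifier). They are linked by
r_whole = r_body/(1 + r_body), which the tests assert. For the batch
pipeline in ratio mode, each radicle region's area is compared against
s_opt as the body-area proxy, since the global pipeline has no per-seed
radicle attribution; per-seed attribution exists only in the boxed
classifier, where each bounding box is processed independently through a
mask provider (default: the package's own color clustering within the
crop; any promptable segmenter can be plugged in behind the same
interface).

N_r is the count of qualifying radicle regions, clamped at N_s; the
germination rate is N_r/N_s, undefined (an error) when no seed is found.

Seed length/width are the major/minor axis lengths of the moment ellipse
(4·√eigenvalue of the pixel covariance), the standard regionprops
convention; collinear pixel sets return width 0 with a warning.

## Evaluation metrics

Box matching is greedy per class in descending confidence (ties broken by
lower x_min, then y_min); a prediction claims the unmatched ground-truth
box with the highest IoU provided that IoU is **strictly above** the
threshold, each truth is claimable once, and unclaimed truths are FN. AP
integrates the right-monotonized precision envelope over recall (the
continuous all-points method, matching the integral definition); a
101-point variant is available by flag. mAP averages defined per-class
APs; a class without ground truth is excluded with a warning. AE is the
mean over images of |yᵢ − yᵢ′|/yᵢ, skipping zero-truth images (the term is
undefined there) with a warning; MAE averages AE over classes. Relative
count error has two named variants: absolute |auto − manual|/manual, and
signed (manual − auto)/manual, whose sign convention makes over-counting
negative. Mask scoring reports TP/FP/FN/TN and Dice, IoU, pixel accuracy
and FPR; two empty masks score as vacuously perfect with a flag. A
convenience sweep averages mAP over IoU thresholds 0.5:0.05:0.95 as a
plain mean; it is not a COCO evaluator.

Annotations are read from Pascal VOC XML (LabelImg dialect, classes
"yes"/"no") and YOLO text; predictions from JSON lines. All in-memory
coordinates are 0-based half-open pixel intervals, and the writers
round-trip exactly (VOC) or within 0.5 px (YOLO's 6-decimal normalized
format).

## Synthetic dishes

The generator emulates what the pipeline's assumptions require and
nothing more: ellipse seed bodies with yellowish coats (R 185–215,
G 150–185, B 45–75, ±8 jitter — every coat pixel keeps R−B > 60 and
G−B > 40), near-white radicles (225–250) grown as exact-pixel-count
capsules from a body tip, a dark noisy background (≤ 50), optional
coat-colored awn fragments under the 200-px noise floor and droplet
highlights under the 20-px radicle floor. A dish holds one variety, so the
body axes are drawn once per dish (semi-major 18–26 px, semi-minor
8–12 px, giving ~500–900 px bodies consistent with the pipeline's pixel
thresholds) and individual seeds jitter by 3% — matching single-variety
assays, where within-dish seed size is near-uniform. Germination is
assigned by exact count (round(p·n) seeds), not Bernoulli draws, so the
expected rate of every dish is deterministic. Touching seeds are rendered
as pairs placed at 0.95× the sum of effective radii, accepted only when
the bodies merge with < 15% overlap; merged indices are recorded so
counting tests know the expected multiplicities. All randomness flows
from one `numpy` Generator seeded by the spec, making images
byte-reproducible.

What the generator does **not** emulate: lens distortion, lighting
gradients, specular highlights on seeds, radicle curvature and entanglement,
seed-coat color variation between overlapping varieties, and shadows.
Passing the synthetic suites therefore demonstrates the pipeline's
correctness under its stated assumptions, not its accuracy on arbitrary
real photographs.

## Problem sizes and defaults

The recovery suites use 20 dishes of 30–60 seeds at 1920×1080 per
condition — the assay's own scale — and run in well under a minute each.
Key defaults: noise floor 200 px, stability gap 30 px, stability run 2,
radicle floor 160, ratio floor 100, T_g 100 px, ratio standard 0.4 (body
variant), IoU threshold 0.5, connectivity 8, counting mode floor. All are
`PipelineConfig` fields and resolution-dependent; users at other imaging
scales should rescale the pixel thresholds proportionally to seed area.

## Known limitations

- Counting relies entirely on area multiplicity: clusters of 3+ seeds or
  strongly overlapping pairs are resolved only as well as sᵢ/s_opt
  rounds, and a dish whose seeds genuinely vary widely in size breaks the
  stable-prefix assumption (the low-confidence median fallback engages).
- The global area standard cannot attribute radicles to seeds; two
  radicles from one seed would count twice.
- Color thresholds assume the imaging-box palette; dishes photographed
  under uncontrolled light need retuned floors.
- The degenerate single-cluster path labels every pixel by the initial
  centers and should be treated as "no seeds found" downstream.
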