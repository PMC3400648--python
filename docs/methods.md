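# Methods

`mldcyto` reduces time-lapse fluorescence movies of nanoparticle-labelled
cells to per-frame point sets ("binary elements", one per quantum-dot
loaded vesicle) and analyses cells entirely through the geometry and
dynamics of those points. This note records the model, the parameters
that matter, the numerical choices made where the procedure left them
open, what the simulator does and does not emulate, and the known
limitations.

## Image reduction

**Focal fusion.** Each timepoint arrives as a stack of focal planes on a
shared pixel grid. The field is tiled into blocks (default 32 px,
configurable); for each block the plane with the largest sum of absolute
horizontal plus vertical intensity differences — the absolute-gradient
contrast measure — is copied into the composite. Only differences
internal to a block are counted, so the choice is independent of
neighbouring blocks; ties go to the lowest plane index, and a block size
larger than the image degrades gracefully to whole-image selection.

**Thresholding.** The background cut-off is θ = µ + σ over all composite
pixels. σ is the population standard deviation of the whole image by
default (a documented choice — sample vs population and whole-image vs
regional are not dictated by the formula; both are exposed in
`PipelineConfig`). An important operating-regime consequence: when
bright vesicle spots occupy an appreciable fraction of the field they
inflate σ, so θ sits several background standard deviations above the
noise mean and background pixels rarely pass. On nearly empty fields
θ falls in the upper background tail and "rogue" noise elements appear
frequently — the sparse limit is outside the method's operational range,
which the threshold-sweep module quantifies.

**Peak finding.** A pixel is an element when it is simultaneously the
maximum of its row profile and of its column profile within an odd
window (default 5 px) and lies above θ. Plateaus of equal maxima yield
exactly one element (lowest row, then column). The 5 px window sets the
resolution limit: vesicles closer than ~window×pixel-size merge into one
element, which lowers per-cell element counts but barely moves cluster
centroids.

## Cell identification

Clustering is Lloyd's algorithm on the element coordinates with fixed
initial seeds (convergence when no centroid moves > 0.5 px, at most 100
iterations; nearest-seed ties break to the lowest centroid id; empty
clusters are dropped with a warning). The first frame is seeded either
from a user file (the procedure's manual mode) or automatically by
connected-component grouping of elements at a 30 µm linking radius; the
mode is recorded in the run manifest. Every later frame is seeded by the
previous frame's centroids with three rules, all configured in µm and
converted through the pixel size:

* an element farther than 30 µm (~3 cell diameters) from every seed
  spawns a new seed at its own position — entering cells and noise are
  indistinguishable at this point and are deliberately both absorbed,
  to be interpreted later from track context;
* a seed with no element within 12.5 µm is removed (cells that left the
  field, stale noise seeds);
* a cluster whose mean pairwise element separation exceeds 15 µm
  (~1.5 cell diameters) is re-clustered with one extra seed placed
  10 px from the centroid, and the split is kept only if the frame's
  mean silhouette improves; the offset direction is toward the
  cluster's farthest member (the direction is genuinely open; this
  choice separates bimodal clusters fastest), and the offset is capped
  at the farthest-member distance so the probe always lands inside the
  cluster's support — without the cap a compact two-element cluster
  placed the probe beyond both points and the trial collapsed.

Both products of an accepted split receive fresh ids: daughters are
treated symmetrically and no cluster silently keeps its parent's
identity through a bifurcation.

Two dispersion statistics are kept per cluster because the procedure
uses both phrasings: the mean over unordered element pairs (drives the
15 µm rule and the mitotic curve) and the mean element-to-centroid
distance (exported alongside).

## Temporal linkage

Cross-frame centroid pairs within 10 µm (the average single-cell
diameter) are visited in ascending distance order; a pair links when the
child is parentless and the parent has fewer than two children. Ties
break lexicographically by (parent id, child id). A parent with two
children is a division candidate; a child no parent reaches is a new
progenitor; a third nearest neighbour is never linked. The published
two-phase description (link all next-frame centroids, then attach
leftover previous-frame centroids within the radius) collapses to this
single greedy pass once each child is restricted to one parent —
a leftover parent's only candidates are already-parented children, so
the second phase can never add a link. Gap closing across skipped
frames is deliberately absent: at 5-minute intervals cells move a small
fraction of their diameter, and a lost centroid is better handled by
the progenitor bookkeeping than by guessing.

## Mitosis detection

Each unbranched track carries an online contraction–expansion detector
over its mean-separation series. A rolling window (default 12 frames =
60 min) of stable samples defines the baseline as its median; a sample
below `contraction_fraction` × baseline (default 0.6) freezes the
baseline and opens the contraction phase; the running minimum is
tracked; the first later sample above the baseline confirms a division.
At the confirmation frame the cluster is force-split (the split
mechanics above, silhouette test bypassed) into two daughter tracks and
the event is recorded with its minimum and confirmation frames. This
realises the published rule — elements are reassigned to daughters when
the separation "surpasses the stable separation distance maintained
prior to contraction" — as a purely online procedure, with the 15 µm
silhouette split and the two-nearest-neighbour tracking signature
acting as fallbacks: a bifurcation *without* curve confirmation is
treated as a cluster correction (the lineage continues through the
nearest child; the other child starts a new progenitor), never as a
division.

A baseline is considered valid only when (i) at least half the window
is filled, so tracks beginning shortly before a division still qualify;
(ii) its median lies in [2.5 µm, 15 µm) — below that range the
"cluster" is an unresolved point pair with no dispersion statistic,
above it the cluster is by the 15 µm rule not a single cell; and
(iii) the median element count in the window is at least 4, echoing the
operating analysis that a centroid is only reliably identified from a
handful of elements. Frames with fewer than two elements carry no
separation measurement: while no baseline exists they are skipped, but
once a valid baseline exists a multi-element cluster collapsing to a
single merged peak is the strongest observable contraction and is
scored as separation 0. These three guards are what keep the detector
quiet on border-clipped cells, noise fragments and merged neighbours.

`frame_of_minimum` (the rounding minimum, typically the cytokinesis
frame ±1) is the event timestamp used for comparisons;
`frame_confirmed` lags it by the few frames the daughters need to move
one baseline apart.

## Lineage, motility and population statistics

Lineage cells are maximal chains of track segments between confirmed
divisions, assembled iteratively (no recursion, so arbitrarily deep
forests are safe). Cells end by division, by loss before the final
frame, or with the movie. Motility vectors are net displacement over
elapsed time in µm/h (matching the lineage-portrait arrows); path
length is exported alongside since a random walk's net speed is far
below its path speed. The doubling time is the two-point estimate
T = Δt / log₂(N₁/N₀) (undefined, and reported as such, when counts do
not grow); the published worked example 41 → 133 centroids over 40 h
gives T = 23.6 h. Mean elements per cluster feed the same formula
inverted for the vesicle halving time. Trees export as nested JSON and
as Newick with branch lengths in hours.

## Operational-range sweep

For each threshold in an ascending list, peak finding and seeded
clustering (spawn/removal rules included, split tests omitted — the
sweep probes identification, not division) are re-run from the same
reference seeds. Reported per threshold: element count, validated
centroid count, and each reference centroid's displacement from its
position at the *highest* (cleanest) threshold — the reference had to
be fixed somewhere, and the cleanest image is the least noise-biased
anchor. SNR is reported as reference spot peak over threshold cut-off,
the ratio convention consistent with the published threshold/SNR pairs
(784 ↔ 2.8, 1100 ↔ 2.0 at a spot intensity of ~2.2 × 10³ units); the
source text never defines SNR explicitly.

## The simulator

The generator emulates the study system: adherent cells on a field of
configurable size, each carrying 10–50 vesicles (default range) on a
perinuclear annulus (radius 3.2 ± 0.6 µm for a 10 µm cell), jittered by
0.3 µm per frame, spread across focal planes with a Gaussian z-profile,
and rendered as 2-D Gaussian spots (σ 0.5 µm) over N(400, 20) background
noise with 12-bit detector saturation at 4095 — saturation matters,
because a mitotically condensed cloud would otherwise render an
unphysically bright blob that drags the global threshold up and starves
every other cell of elements. Spot brightness is `snr` × (background
mean + one background SD), uniform ±30 % per vesicle; the realised
peak-to-threshold ratio matches the configured SNR on sparse fields and
degrades gracefully as spot variance inflates θ on dense ones.

Dynamics: cells random-walk with Gaussian steps whose mean speed is
`motility_um_per_h` (default 6 µm/h); overlapping cells push each other
apart to a 12 µm contact distance (≤ 2 µm/frame) — adherent cells do
not interpenetrate, and without exclusion neighbouring vesicle clouds
interleave irrecoverably. Inter-mitotic times are N(23, 2²) h (floored
at 8 h); initial cells carry uniform ages so the population divides
asynchronously. Approaching division the vesicle cloud contracts
linearly to 0.25× over 30 min; at cytokinesis the vesicles partition
binomially (re-drawn so each daughter gets at least one when possible —
vesicle sets always partition exactly); daughters then separate at
36 µm/h relative for 20 min (the fast anaphase/abscission phase) and
12 µm/h until 30 µm apart, while their clouds re-expand over 60 min.
Cells can enter at the field border (Poisson rate, default off) and
leave when they cross it. Identical seeds give bit-identical pixels and
ground truth, and the truth-only run matches the rendered run's truth
exactly (separate RNG streams).

**What the simulator does not emulate** — and what passing tests
therefore do not certify on real data: diffraction and optical
aberrations, photobleaching (quantum dots are photostable, so none is
modelled), spatially varying background and vignetting toward the field
edge, cell shape (cells are isotropic point-cloud carriers), active
vesicle transport within the cytoplasm, and true confluence mechanics
beyond pairwise exclusion. Confluent identification is the technique's
own stated limiting factor and is equally the limit here.

## Validation conditions and problem sizes

The heavy validation scenario runs the full pipeline on simulated 40 h
movies at 5-minute frames (481 frames), 512×512 px at 0.5 µm/px
(a 256×256 µm field — the px scale chosen so ~20 initial cells can
proliferate through two rounds without confluence; every distance rule
is specified in µm, so the pixel scale is consistent throughout), SNR
2.5, 16–50 vesicles per cell, IMT 23 ± 2 h, initial spacing ≥ 38 µm so
the automatic first-frame seeding (30 µm element linking) resolves all
starting cells. Five movies back the test suite; the acceptance script
simulates three. Division detection is scored at a ±3-frame tolerance
against ground-truth cytokinesis, using the rounding-minimum frame;
recall is measured over divisions whose contraction and re-expansion
both lie inside the movie (7 frames from either end), precision over
all detections against all true divisions. Lineage topology is compared
for isolated families — those never within 16 µm of another family
(above the 12 µm contact distance), never exiting, with all divisions
observable. A 100-frame truth-level simulation (12 µm/h motility,
≥ 60 µm spacing) checks identity preservation, and a single 38-cell
frame (380×330 µm) drives the operational-range sweep.

## Degenerate inputs and tie-breaks

Empty frames yield empty cluster states and end all tracks; an empty
first frame defers seeding until elements appear. All-coincident
elements collapse to one cluster, survivors reported. Negative
thresholds clamp to zero. Single-cluster frames define the mean
silhouette as 0 with a warning; singleton members score 0. Ties: plane
selection → lowest plane; nearest seed → lowest centroid id; link order
→ (parent id, child id); plateau peaks → lowest y then x. A forced
split whose products do not both re-link to the mother is discarded as
a division (logged) rather than emitting an inconsistent event.

## Known limitations

* The sparse limit (a few cells in a large field) puts θ = µ + σ in the
  background tail; rogue elements then dominate and identification
  degrades, as the sweep module shows. The method wants a reasonably
  populated field.
* At 0.5 µm/px the peak window merges vesicles aggressively; mean
  separations are measured on merged peaks and the contraction dip can
  pass through a one-element frame, handled by the collapse rule above.
* Divisions in the first ~30 min of a movie (no observable baseline) or
  the last ~20 min (no observable re-expansion) cannot be confirmed by
  any curve-based rule.
* Motility vectors of cells born late are measured over short spans and
  are noisy; the flag column marks single-frame cells.
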