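# Methods

`leukotrace` quantifies neutrophil (PMN) trafficking on an endothelial
monolayer from label-free phase-contrast time-lapse video. This note
documents the models and procedures behind each stage, the parameters that
matter, the choices made where the design was genuinely open, and what the
synthetic test substrate does and does not establish about real data.

## Imaging model and standardization

Input is a grayscale TIFF stack, nominally 450 frames at 0.25 Hz (4 s
frame interval), 16-bit 2048×2048. Standardization converts to 8-bit,
downsizes to 1024×1024 by bilinear interpolation, and histogram-equalizes
each frame over 256 bins.

- **16→8-bit mapping** is a linear min-max rescale over the *whole stack's*
  range, not per frame, so slow temporal brightness trends are preserved
  until equalization (which is what actually removes them). A zero-range
  stack maps to 0.
- **Equalization scope** is per-frame by default (`scope="frame"`); the goal
  is to stabilize brightness and contrast both across videos and through a
  video's duration, which per-frame equalization achieves directly. A
  per-stack variant (`scope="stack"`) is available when relative frame
  brightness is itself of interest.
- Stacks are split into contiguous sub-stacks whose length matches the
  worker count (a 450-frame video on 18 workers → 25 sub-stacks of 18) for
  parallel segmentation. Parallel output is bit-identical to sequential
  output by construction: per-frame inference is deterministic and chunks
  are reassembled in frame order.

## Pixel classification

Each pixel of a standardized frame is classified into four classes —
endothelial background (0), luminal "static" PMN (1), luminal "probing"
PMN (2), transmigrated/abluminal PMN (3) — by a random forest over a fixed
21-feature bank: raw intensity; Gaussian blurs at σ ∈ {1,2,4,8,16} px;
gradient magnitude at each σ; difference-of-Gaussians of consecutive σ
pairs; and both Hessian eigenvalues at σ ∈ {1,2,4} px. The bank covers
intensity, edges, scale and ridge-ness — the cues that distinguish
phase-bright rounded luminal cells from phase-dark amorphous transmigrated
cells and from the textured monolayer. Borders are reflected; the feature
order is fixed.

The forest uses 200 trees, √(n_features) candidate features per split and
unlimited depth — conventional defaults for this classifier family. Sparse
ground-truth masks drive training: values 0–3 label pixels, 255 means
unlabeled; unlabeled pixels are ignored, never treated as background.
Labeled pixels are pooled over augmented copies of each (frame, mask) pair
(horizontal/vertical flips, 90° rotation, a Gaussian-blur copy and a
brightness-jitter copy) and capped at 10,000 per class for balance and
CPU-scale training times. The model reports its out-of-bag (OOB) error;
because OOB is computed on the class-balanced training distribution,
sanity comparisons against held-out data are made on class-balanced
samples of the held-out truth.

Argmax ties break toward the lowest class index. A two-class reduced
problem is accepted with `allow_subset=True` (used for calibration toys);
the full pipeline requires labeled pixels in all four classes and raises
otherwise, listing the absent classes.

## Detection and state

PMN-class pixels (classes 1–3) are merged and connected components
extracted with 8-connectivity — phase halos make diagonal contact common.
Components with area strictly greater than 600 px are kept; smaller ones
are noise. No hole filling or morphological smoothing is applied (a
documented extension point). Centroids are unweighted pixel-center means,
x = column, y = row, 0-based; the equivalent disk radius is √(area/π).

A detection is **abluminal** iff strictly more than 50% of its pixels carry
the transmigrated class; exactly 50% stays luminal.

The per-frame **transmigration ratio** is pixel-based and bulk:
r = T/(T+L), where T and L are transmigrated- and luminal-class pixels
summed over retained detections. The fraction form is bounded in [0,1];
the odds form T/L is available via `denominator="luminal"`. A frame with no
PMN pixels yields a missing value, not 0. The **steady-state regime** is
the longest suffix of the ratio series whose rolling least-squares slope
(window 30 frames = 120 s) stays below 10⁻³ per frame in magnitude; if no
suffix qualifies the last half of the series is used with a warning. The
regime mean is the reported transmigration ratio. The slope criterion is
this package's own construction — plateau detection has no canonical
recipe — and both the window and threshold are exposed.

## Single/multiple classification and counting

Area or shape alone cannot separate single PMNs from clusters (activated
cells are amorphous), so each detection's **binary mask crop** — the
component centered on its centroid, padded square, resampled to 32×32 by
local averaging and re-binarized — is classified single/multiple by a
compact CNN with the classic LeNet-5 layout: conv(6@5×5) → pool(2) →
conv(16@5×5) → pool(2) → dense(120) → dense(84) → dense(2, softmax). Using
binary masks rather than intensities makes the decision depend only on
segmentation geometry. The network is small enough that it is implemented
directly on NumPy (im2col convolutions, max pooling, ReLU, Adam on
cross-entropy); training takes seconds to minutes on one CPU. Training
uses a stratified 80/20 split, 25 epochs of Adam (lr 10⁻³, batch 32), and
dihedral (flip/rotation) augmentation of the training portion only;
`validation_error` comes from the held-out crops.

Cluster counts divide the cluster's pixel area by the mean area of
same-frame detections classified "single", rounded to the nearest integer
with a floor of 2 (a "multiple" holds at least two cells). A frame with no
singles falls back to the running mean of the trailing 10 frames, then to
a configured global mean. Per-frame totals are the sum of per-detection
estimates.

## Tracking

Centroids are linked frame-to-frame by greedy nearest-neighbor assignment:
per frame, all (active fragment, detection) pairs within the gate are
sorted by distance (ties: lower detection id, then older fragment) and
assigned greedily, each fragment and each detection used at most once. No
motion prediction is applied; distances are measured from the fragment's
last known centroid. Global/probabilistic linking is deliberately out of
scope — the method is conservative by design and produces track
*fragments*.

**Gate.** A fragment last seen g frames ago may claim a detection within
11·g px, up to 55 px at the maximum gap of 5 frames. The phrasing "55
pixels radially over 5 frames, 11 pixels added per future frame search"
admits a fixed-55-px reading as well; that alternative is available via
`GateRule(fixed_radius=True)`. The growing-gate reading is the default
because it is the one consistent with "added per future frame".

**Clusters and overlaps.** When two or more tracked cells converge into
one qualifying cluster detection, their fragments end (`merged`) and a
single fragment follows the cluster's common centroid; when the cluster
dissolves, the cluster fragment ends and fresh fragments start
(`split_from_merge`, parent set to the cluster fragment). Identity is not
reassigned across merges. A detection qualifies as a cluster "bulk body"
when its estimated count is ≥ 3 or its area is ≥ 3× the frame's mean
single area (the size threshold is otherwise unspecified; both constants
are configurable). A cluster fragment only follows cluster detections: on
dissolution it terminates rather than adopting one of the separating
cells.

**State splitting.** Fragments are split at every luminal/abluminal state
change; each maximal constant-state run becomes a sub-fragment chained via
`parent_fragment`, so concatenating a chain reconstructs the parent
sequence exactly. No flicker smoothing is applied by default (an optional
3-point majority filter is a documented extension); a fragment's bulk
state is the majority state of its points, ties resolved abluminal.

## Motility

Fragments longer than 100 frames (400 s) are summarized by:

- **Meandering index**: net displacement / total path length ∈ [0,1];
  a zero-length path is defined as 0. Fragments with MI < 0.1 are grouped
  "non-reactive".
- **MSD**: time-averaged over all overlapping lag pairs, lags up to
  τ_max = 120 s (30 lags at 4 s frames). Overlapping pairs are the
  conventional, statistically efficient choice; they correlate residuals
  across lags, which is one plausible source of the persistence–length
  coupling surfaced as a diagnostic below.
- **Speed S and persistence P** from an unweighted nonlinear least-squares
  fit of the persistent-random-walk (Dunn) model
  MSD(t) = 2S²P[t − P(1 − e^(−t/P))], parameterized in log-space with
  multistart over P₀ ∈ {5, 20, 80, 320} s, S₀ from the first-lag ballistic
  slope, and bounds S ∈ (0, ∞), P ∈ (0, 10⁴ s]. In the t ≪ P limit the
  model is ballistic (S²t²), in the t ≫ P limit diffusive (2S²Pt); a
  near-ballistic curve therefore pins P at the upper bound and the fitted
  P is a lower bound. Non-convergent fits are flagged and excluded from
  group statistics with a logged count.

Fits are per-fragment (not pooled per condition); group summaries report
mean ± SEM of S, P and MI for: all long fragments, the 15 longest, 15
random (seeded), luminal vs abluminal by bulk state, and
non-reactive/reactive. Units default to px and s; µm conversion applies
only when the pixel size is configured. Fitted persistence is known to
correlate inversely with fragment length in this estimator family; the
package surfaces per-fragment length alongside P̂ and does not correct for
it.

## Synthetic data generator

The generator produces seeded phase-contrast-like stacks with complete
ground truth (dense 4-class masks, per-frame cell tables, true tracks,
counts and transmigration fractions), emulating:

- **Photometry**: static band-limited background texture (smoothed noise,
  mean 120, contrast 10 on the 8-bit scale); luminal static cells as
  bright discs (+70) with a Gaussian halo rim (+25, width 2.5 px); probing
  cells with an oscillating boundary and reduced body brightness (factor
  0.6 — flattened, actively probing cells lose phase brightness);
  transmigrated cells as darker (−45) amorphous blobs with low-order
  Fourier boundary perturbation (amplitude 0.22); additive Gaussian noise
  (σ = 5).
- **Geometry**: cell radii ~ N(16.5, 1.5²) px clipped below at 15 px — an
  imaged-PMN size floor that keeps every single cell above the 600-px
  detection noise area, as real PMNs at this magnification are. A
  configurable fraction of cells is placed touching an anchor cell and
  moves with it, producing persistent clusters of known multiplicity.
- **Transmigration**: selected cells blend linearly bright→dark over 5
  frames (20 s) from a random onset; the ground-truth state flips at the
  half-blend point. Reverse transmigration is not modeled, so the true
  transmigrated fraction is monotone non-decreasing. Mid-blend cells are
  nearly invisible by construction — the same intermediate-phase blind
  spot the imaging modality has.
- **Motion**: a 2-D Ornstein–Uhlenbeck velocity process with relaxation
  time P and per-component stationary variance S²/2, sampled with the
  exact discrete-time update for the integrated OU process (jointly
  Gaussian position/velocity increments). Its closed-form 2-D MSD equals
  the Dunn model with parameters S and P exactly, which makes motility
  parameter-recovery tests sharp rather than approximate. Defaults
  S = 0.15 px/s, P = 40 s per state; 25% of cells are immobile. Boundaries
  are reflective, so the population is conserved every frame.

Training fixtures mimic manual annotation: sparse masks sample a capped
random subset of the dense truth per class, with half of the background
labels drawn from a 6-px rim band around cells (annotators label around
cells, and the phase halo lives there). Label frames are drawn from
several scenario variants with distinct backgrounds — a segmenter trained
on a single video memorizes that video's background texture and does not
transfer. Single/multiple crop datasets are generated from the same
cell-shape model (one blob vs 2–3 overlapping blobs).

**What the synthetic substrate does not show.** The generator does not
model optics-accurate phase contrast (no point-spread simulation), cell
deformation during crawling, focus drift, debris, or reverse
transmigration. Passing tests demonstrate that each algorithm is correct
against its own contract and that the pipeline recovers known truth under
the stated phenomenology; they do not certify error rates on experimental
recordings, whose difficulty (activated-cell morphology, variable
illumination) is only coarsely emulated.

## Validation harness

The harness replicates the manual-validation protocol with simulator truth
standing in for manual counts (stated in every report header): counts are
compared at the first frame and every 30th frame (1-based 1, 30, 60, …),
the metric is mean absolute percent error, and residuals are screened for
sign bias with an exact binomial CI on the fraction of positive residuals.
Distribution comparisons use the standard two-sample Kolmogorov–Smirnov
test, Student's t-test, and one-way ANOVA. A per-fragment bulk-state error
versus truth is computed analogously to the counting check; no numeric
target is asserted for it since the published figure is data-specific.

### Problem sizes

Default test and acceptance scenarios run at 512×512 × 120 frames with
~30 cells — a scale at which the full train-segment-count loop completes
in minutes on one CPU while every mechanism (clustering, transmigration,
noise) is exercised. Parameter-recovery studies use 200 fragments × 450
frames per condition over a 3×3 (S, P) grid; the pilot Monte-Carlo
results motivating the 10% (speed) and 25% (persistence) recovery
tolerances are in `pilot_dunn_recovery.json` (regenerate with
`scripts/pilot_dunn_recovery.py`).

## Numerical and degenerate-input choices

- Zero-range stacks standardize to 0; frames with no PMN pixels emit a
  missing transmigration ratio; a zero-length path has MI 0.
- Argmax ties in segmentation choose the lowest class index; greedy
  linking ties resolve by lower detection id then older fragment.
- The Dunn fit is performed in log-parameter space for positivity; its
  residual tolerances are 10⁻¹²; "converged" reflects the optimizer's
  success flag of the best multistart.
- Seeds: every stochastic component (simulator, training subsampling,
  augmentation jitter, network init, batch order, random-15 selection)
  derives from an explicit integer seed; repeated runs are bit-identical.

## Known limitations

- Intermediate transmigration phases are not detectable (rapid ~20 s
  events); state flips are observed, not resolved.
- Identity is not preserved across merges; reverse transmigration cannot
  be called from fragments.
- The luminal static/probing distinction rests on morphology and
  brightness; it is the weakest class boundary and errors there do not
  affect counting or the transmigration ratio (both merge the luminal
  classes).
- The 600-px noise floor is resolution-dependent (tuned for 1024²-scale
  imagery); it is a config key, not a constant.
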