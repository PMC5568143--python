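# Methods

## Scalar maps from diffusion tensors

The input is either a 6-component symmetric tensor volume or three
eigenvalue maps (mm²/s), plus a binary cerebrum mask. Tensor fitting from
raw diffusion-weighted images, eddy-current correction, brain extraction and
cerebellum removal are upstream concerns: the package consumes already
masked tensor/eigenvalue volumes, and the mask is the single source of
"cerebrum" membership for every downstream computation.

Eigendecomposition uses `numpy.linalg.eigvalsh` on the symmetric per-voxel
matrices; eigenvalues are sorted descending. MD, FA and the (p, q)
decomposition follow the definitions in the README; `p² + q² = Σλᵢ²` is an
exact algebraic identity and is enforced in tests at 1e-10.

**Negative eigenvalues** (noise or upstream fit artefacts) are retained,
counted and logged, not clamped: clamping would silently bias the p and q
statistics, and the cohort-level percentile clamping applied before
segmentation already suppresses outliers. This is a policy choice — how such
voxels were handled upstream in real pipelines is generally unstated.

## Cohort normalisation

The 1st and 99.99th percentiles (linear-interpolation definition, fixed for
reproducibility) of the pooled in-mask p and q values define clamping
bounds; values outside are set to 0 or 1, the rest scaled linearly into
[0, 1]. Clamped voxels are **retained**, not discarded, so spectrum
denominators always equal cerebrum volume; a fit on fewer than 10⁴ pooled
voxels warns that the 99.99th percentile is unstable, and a degenerate
(constant) distribution is an error.

Normalisation and clustering are fitted on the pooled cohort — all subjects,
all timepoints, ideally spanning healthy to damaged brains — because spectra
are only comparable under a shared partition of (p, q) space. The fitted
model is serialised to JSON and applied unchanged to new scans.

## k-medians segmentation

* **Initialisation** is deterministic: quartile boundaries of normalised p
  and q define a 4×4 grid of cells of roughly equal occupancy; each initial
  centroid is the component-wise median of its cell; empty cells reseed at
  the cell's geometric centre.
* **Iteration** alternates nearest-centroid assignment (Euclidean distance
  in [0,1]²; ties to the lowest canonical label) with centroid updates to
  the component-wise (marginal) median of the assigned samples — "median" is
  read per-coordinate, not as the geometric (spatial) median, matching the
  recalculation of median p and median q separately.
* **Termination**: zero reassignments, or 250 iterations (the fit records
  `converged` and `iterations_run`). On all synthetic cohorts tested,
  convergence occurs within ~30–100 iterations.
* **Empty clusters** during iteration are reseeded to the sample farthest
  from the cluster's previous centroid and logged. This situation is normal
  when the data are a few tight clouds rather than a continuous density.
* **Objective**: the within-cluster sum of squared distances J is recorded
  after every assignment step, together with J of the previous labelling
  under the same centroids. The assignment pass provably never increases J
  at fixed centroids, and that is the monotonicity asserted in tests. The
  full J sequence across iterations is *not* guaranteed monotone, because
  the median update optimises an L1 criterion, and non-monotone steps do
  occur in practice; convergence is guaranteed by the termination rule, not
  by a Lyapunov argument.
* **Memory**: pooled samples above a cap (default 5×10⁶) are subsampled by a
  deterministic stride with a seed-derived offset; the fit targets the
  empirical (p, q) density, which uniform striding preserves.

k = 16 segments is the standard configuration (a pragmatic balance between
resolution of the (p, q) plane and statistical power); the code accepts any
square k.

Segment labels 1..16 are assigned canonically by ascending centroid p, ties
by ascending q — low labels are low-isotropy (tissue-like), high labels
high-isotropy (CSF/damage-like). Published figures use a semantic numbering
derived from anatomical inspection that no rule reproduces; θ is invariant
to any fixed relabelling applied to all spectra, so the choice is purely
presentational.

## Spectra, θ and the reference search

A spectrum is 100·(voxels in segment i)/(in-mask voxels). θ between two
spectra is the arccosine of their normalised dot product, reported in
**degrees** (the cosine is clamped to [−1, 1] before arccos; only relative
magnitudes matter for the biomarker, and degree-scale numbers are the
convention in the literature this implements). The spectrum operation
normalises within whatever mask produced the segmentation, so
damage-restricted spectra (e.g. within a lesion mask) follow the same code
path.

The reference search iterates A ← argmaxₓ θ(A, X) from a seeded random
start until the trajectory enters a 2-cycle (A_t = A_{t−2} ≠ A_{t−1}); the
terminal pair is mutually farthest. Argmax ties break to the lowest
spectrum index; a longer cycle (possible only under exact ties) is an
error listing the cycle. Which pair member is "least damaged" is decided
by the **damage score** d(S) = Σᵢ sᵢ·pᵢ/100, the spectrum-weighted mean
normalised centroid isotropy: CSF- and damage-like segments sit at high p,
so the smaller score marks the healthier scan. This disambiguation rule is
a design choice of this package (cohort studies typically knew which scan
was the healthy control); a CLI flag `--reference-id` pins an external
reference instead.

Per-subject annualised θ change is a descriptive OLS slope of θ on years
since baseline; subjects with one timepoint get a missing value. Cohort
inference (mixed-effects models of θ against cognition) is out of scope.

## Colour maps

Within-segment medians of T2 (from the b0 volume), p and q are ranked 1
(lowest) to 16 (highest), ties broken by segment label; the ranks drive the
red (T2), green (p) and blue (q) channels as round(255·rank/16). The
rank-to-byte mapping is this package's single fixed rendering convention;
any monotone mapping preserves the semantics. Without a T2 map the red
channel repeats the p ranks and the output is flagged.

## DTI histogram comparators

Spurious CSF voxels are removed from the white-matter mask first (MD
strictly above 0.0026 mm²/s). Histograms use fixed ranges and widths — MD:
0–0.004 mm²/s in 4×10⁻⁶ bins; FA: 0–1 in 0.001 bins (1000 bins each) —
half-open bins with the last bin closed, normalised by the in-range count;
out-of-range values are excluded but counted. NPH is the maximum normalised
frequency; the median is the voxelwise median of the raw values, never of
the binned data, to avoid quantisation. Masks are assumed co-registered to
diffusion space.

## Synthetic phantom cohort

The generator emulates a longitudinal SVD-like cohort at the level the
biomarker sees: the voxelwise (p, q) distribution and its drift with
disease, not the imaging physics.

* **Classes**: GM, WM, CSF, GM/CSF boundary (partial volume) and WMH-like
  damage, each a truncated Gaussian in (p, q) with literature-scale means
  (e.g. MD ≈ 0.8, 0.72, 3.0, 1.2, 1.7 ×10⁻³ mm²/s respectively; WM the most
  anisotropic; damage less anisotropic and more isotropic than healthy WM).
  Baseline volume fractions 0.40 / 0.35 / 0.12 / 0.08 / 0.05. These are
  plausible values chosen for qualitative fidelity, not fitted to any
  cohort. `well_separated=True` shrinks all standard deviations eightfold
  (below ~0.02 in cohort-normalised units) for parameter-recovery tests.
* **Progression**: a damage fraction d per scan converts each WM voxel to
  damage and each GM voxel to boundary with probability d — healthy tissue
  is lost to white-matter damage and to CSF-boundary partial volume. The
  default cohort schedule spreads baseline severity 0–0.25 across subjects
  and adds 0.05 per timepoint.
* **Geometry**: a 32³ ellipsoidal "cerebrum" (~13k voxels) with concentric
  class shells (ventricular CSF core outward to a boundary rim), or a
  spatially random mixture. Spatial arrangement affects only colour-map
  visuals; spectra depend only on class fractions.
* **Tensors** are axially symmetric (prolate): MD = p/√3, δ = q·√(2/3),
  λ₁ = MD + δ, λ₂ = λ₃ = MD − δ/2, which reproduces the sampled (p, q)
  exactly and keeps λ₃ ≥ 0 whenever q ≤ √2·p (enforced at model
  validation). Orientation is irrelevant because every derived quantity is
  rotation-invariant.
* **T2-like channel**: class-dependent constants plus Gaussian noise, just
  enough to exercise colour-map ranking.
* **Reproducibility**: each phantom's random stream derives from the cohort
  seed and its subject/timepoint indices; the same seed gives bit-identical
  volumes.

What the phantoms deliberately do **not** model: Rician noise floors,
acquisition artefacts, partial-volume continua, spatial correlation of
damage, registration error, or realistic anatomy. Passing tests therefore
demonstrate the correctness and monotone damage response of the *pipeline*,
not clinical sensitivity on real MRI.

## Problem sizes and numerical choices

Test and acceptance runs use ellipsoid phantoms of 20³–36³ grids (≈3k–19k
in-mask voxels) and cohorts of 4–40 scans; a pooled fit of ~4×10⁵ samples
converges in well under a minute on one CPU. Percentiles are the
linear-interpolation definition; distances are Euclidean in normalised
units; all assignment tie-breaks go to the lowest canonical label; FA of an
all-zero voxel is defined as 0. Angles near 0° carry O(√ε) arccos noise
(~10⁻⁶ degrees), below any scientifically meaningful difference.

## Known limitations

* The canonical segment numbering will not match published semantic
  numberings (θ is unaffected).
* k-medians converges to a local optimum of a heuristic iteration; with few
  very tight clusters and a pooled cohort lacking damaged scans, small
  classes can share a segment. Pooling scans that span the healthy-damaged
  range (as the method prescribes) avoids this in practice.
* The damage score used to pick the "least damaged" pair member assumes
  damage raises mean isotropy; pathologies that lower isotropy would need a
  pinned external reference.
* Whether out-of-percentile voxels should be clamped or dropped is
  ambiguous in the source literature; clamping is the default and
  `--drop-clipped` is intentionally *not* offered on the spectrum path —
  dropping would change spectrum denominators between scans.
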