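# Methods

This note documents the models, algorithms, numerical choices and
limitations behind `punctakit`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinate conventions

Stacks are `(z, y, x)` arrays with voxel sizes `(dx, dy, dz)` in µm; confocal
z-steps are typically much coarser than the lateral pixel size (e.g. 1.4 µm
at 20×, 0.45 µm at 60× vs ~0.2 µm laterally), so *every* distance used by
clustering, colocalization and detection separation is computed in physical
micrometres. Voxel indices are 0-based and address the voxel **center**;
`origin` is the physical position of voxel (0,0,0). Rendered stacks tile
their volume with voxel centers at half-voxel offsets. Stacks missing a
voxel-size source (sidecar JSON or TIFF tags) are refused rather than given
a default: a silently wrong axial step changes every downstream cluster
fraction.

## Friends-of-friends clustering

Link rule: `d ≤ b` with `b` the linking length. The inclusive comparison is
deliberate — exact ties have probability zero on continuous coordinates but
occur routinely on gridded or rounded data, and inclusive linking makes the
partition stable under coordinate rounding. A `strict` switch restores
`d < b`. `min_cluster_size = 2`: a "cluster" must have at least two members;
singletons are reported as non-clustered (label 0). Cluster ids are assigned
by decreasing size with ties broken by smallest member index, making outputs
deterministic and diffable.

`fof_bruteforce` evaluates all O(n²) pairwise distances and is the
trusted reference. `fof_grid` hashes points into cubic cells of edge `b`
(a pair within `b` can never span more than one cell per axis), scans only
the 13 lexicographically forward neighbor offsets plus the home cell so each
pair is examined once, and merges with union-find (path compression, smaller
root wins — determinism again). Only occupied cells are stored, so memory is
O(n). The two implementations are asserted label-identical across hundreds
of random Poisson/Thomas instances up to n = 5000 and linking lengths
0.5–4 µm, and additionally against an independent KD-tree + sparse-graph
oracle in the unit tests.

The fraction-clustered curve over increasing `b` is non-decreasing because
link graphs are nested; this monotonicity, plus permutation, rigid-motion
and joint-scaling invariance, are property-tested.

## Spot detection

The detector replaces an interactive commercial step with an explicit,
testable definition:

1. **Gamma.** `out = M (in/M)^{1/γ}` with `M` the dtype ceiling for integer
   stacks (result rounded half-up to the same dtype) and the data maximum
   for float stacks (no rounding). γ = 1.79 is carried as the conventional
   default of record; γ = 1 is the identity. The transform is monotone, so
   detection ranks are unchanged; it compresses the dynamic range, which
   lowers the relative quality of dim spots.
2. **Blob filter.** Negated Laplacian of Gaussian at per-axis voxel scale
   `σ_axis = (diameter/(2√3)) / voxel_size_axis`, i.e. spherical in physical
   space on anisotropic grids. `diameter/(2√3)` is the LoG scale matched to
   a blob of the given diameter. The default expected diameter (0.6 µm) is a
   conventional synaptic-punctum scale; it is a user parameter, and a
   warning is emitted when it is under twice the largest voxel size (the
   blob is then under-sampled along that axis).
3. **Maxima.** Voxels equal to the maximum over an ellipsoidal physical
   footprint; candidates are then greedily accepted strongest-first with a
   physical minimum separation (default = expected diameter). Equal-height
   candidates are ordered by (z, y, x) index, so plateaus resolve to the
   lexicographically smallest voxel — a stated, reproducible tie-break.
4. **Quality.** `100 × response / max response` over the stack: the
   strongest spot always scores 100, scores are linear in blob intensity on
   zero background (LoG linearity) and invariant to global intensity
   scaling. The default threshold 80 is therefore *relative*; quantitative
   workflows that must keep dim spots should lower it (the pipeline's
   image-path uses 10 in its test configuration).
5. **Localization.** Per-axis 3-point quadratic interpolation of the LoG
   response around the peak, clamped to ±0.5 voxel, then converted to
   physical coordinates.

Because quality is normalized within each stack, it is a relative score;
comparing absolute quality across stacks with different content is not
meaningful. This mirrors how interactive thresholds are actually used (set
per acquisition batch) but is a modelling choice, not a claim about any
proprietary metric.

## Synthetic data

The generators define the conditions under which the pipeline is validated:

* **Poisson fields** — homogeneous rate λ: count ~ Poisson(λV), uniform
  coordinates. The null model for clustering statistics.
* **Thomas fields** — Poisson parents at rate κ, Poisson(µ) offspring per
  parent displaced by an isotropic Gaussian σ. Parents are drawn in a box
  padded by 4σ per side so boundary clusters are not depleted; offspring
  outside the volume are discarded. Expected count ≈ κµV for σ ≪ extents.
* **Renderer** — each punctum is a separable anisotropic Gaussian blob
  (default PSF-like σ = 0.3/0.3/0.6 µm) accumulated over a ±5σ window
  (truncation < 3·10⁻⁶ of blob mass); optional Poisson shot noise or
  additive Gaussian noise (clipped at 0). Noiseless total intensity matches
  the analytic Gaussian mass inside the box to well under 1% at the default
  sampling. Not modelled: realistic PSFs (Airy/Gibson–Lanni), spectral
  bleed-through, autofluorescence, depth-dependent aberrations — so passing
  round-trip tests demonstrates algorithmic correctness, not robustness to
  real optical artifacts.
* **Colocalization pairs** — exactly `round(n_a · f)` A objects are placed
  strictly inside the match radius of distinct B objects (B kept at pairwise
  separation > 3r; unmatched A kept > 2r from every B), so centroid matching
  recovers `f` exactly in both directions. Infeasible packings raise rather
  than silently violating the construction.
* **Experiment designs** — one Thomas field per (animal, hemisphere,
  section, site); defaults follow the common design of two sections × three
  sites per hemisphere. A mean-one lognormal per-animal multiplier (sd 0.2)
  on base density models inter-animal variability, which is exactly what
  control-hemisphere normalization must remove; treatment multiplies the
  treated hemisphere's parent intensity (count effect) and/or mean offspring
  (clustering effect).

Default densities (parent intensity 0.002/µm³, µ = 8, σ = 0.5 µm in a
50 × 50 × 10 µm site → ≈400 puncta) are arbitrary in the sense that no
measured tissue density is implied; they were chosen once so that a 2 µm
linking length produces *partial* clustering (matched-Poisson fraction ≈
0.1–0.3, Thomas ≈ 0.9–1.0), the regime where the statistic is informative.

All generators take explicit integer seeds and are bit-reproducible; there
is no global random state.

## Statistics

Aggregation is the plain mean over all sites and sections within a
hemisphere; animals missing a hemisphere are excluded with a warning (they
cannot be normalized). Normalization divides the treated value by the same
animal's control mean for the same area; a non-positive control mean is an
error, not a silent drop. The normality gate runs Shapiro-Wilk on each group
at α = 0.05 (configurable; the threshold is a convention, and requiring
*both* groups to pass for the t test is the conservative reading of
"test accordingly"). Constant samples are treated as maximally non-normal
(gate p = 0) rather than an error. Mann-Whitney uses the exact null
distribution for tie-free groups of ≤ 20 and the tie-corrected normal
approximation otherwise; the exact path is verified against full enumeration
of rank assignments for group sizes ≤ 7. Unpaired tests are used on
normalized values because the within-animal pairing is consumed by the
normalization step. No multiple-testing correction is applied across
areas/markers; p-values are reported exactly and interpretation is left to
the user.

The pipeline's calibration is itself measured: over 2000 simulated null
experiments (6 animals per cohort, no treatment effect) the gated test's
rejection rate at α = 0.05 must fall inside the 95% binomial CI around 0.05,
and a simulated halving of puncta density must be recovered as a normalized
treated mean of ≈0.5. With 6 + 6 animals the gate selects the t test most of
the time (normalized count ratios are close to normal); the Mann-Whitney
branch engages on outlier-contaminated draws.

## Pipeline runs

`run_pipeline` simulates a treatment cohort and a sham cohort (the sham arm
shares every design parameter but has effect factors 1), measures puncta
count and fraction clustered per site, and compares the cohorts' normalized
values. Cohort seeds derive deterministically from the single run seed, and
`summary.json` is written with sorted keys so identical configs produce
byte-identical summaries. By default the simulated coordinates are clustered
directly; `render_and_detect: true` renders every site into a stack and
re-detects before clustering, exercising the full image path (useful for
validating detection settings, disproportionately expensive for routine
statistical simulation — 12 stacks per animal).

Stage failures abort with the stage name attached and leave completed
outputs on disk.

## Known limitations

* Detection quality is stack-relative; absolute intensity comparisons across
  stacks should use the raw `intensity` field, not `quality`.
* The colocalization radius criterion is a proxy for visual "enwrapped"
  judgements; no morphological overlap is computed (and pixel-based
  coefficients like Pearson/Manders are deliberately out of scope — they
  answer a different question).
* The renderer's simplified optics mean detection performance on real
  stacks will be worse than the round-trip tests; the tests bound algorithmic
  error, not imaging noise.
* FOF results depend on puncta being in physical µm; feeding slice indices
  as z silently changes cluster fractions, which is why the CSV schema
  rejects coordinate columns without a `_um` suffix.
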