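# Methods

## The polymer model behind the generator

Chromosome traces are modeled as fractional Brownian motion (fBm) in each
spatial axis, evaluated at the genomic coordinates of the probe regions
(Mb).  fBm with Hurst index `H` has increments with
`Var[B(t) − B(u)] = |t − u|^{2H}`, so with per-axis standard deviation σ at
1 Mb the expected 3D separation between loci `g` Mb apart is

    E‖Δ‖ = σ · g^H · E‖z‖,      E‖z‖ = √2 · Γ(2)/Γ(3/2) = 2√(2/π) ≈ 1.5958

(the mean of a chi distribution with 3 degrees of freedom).  Setting
`σ = a / E‖z‖` makes the mean pairwise distance follow `d(g) = a·g^s`
exactly with `s = H`, which is the quantity the analysis side fits.  `H =
0.5` reduces to a Gaussian random walk.  Sampling is exact: the R×R fBm
covariance `K_ij = (t_i^{2H} + t_j^{2H} − |t_i−t_j|^{2H})/2` is
Cholesky-factorized (R ≤ 22, so this is cheap and needs no spectral
approximation) and each axis drawn independently.  A 1e−12 diagonal jitter
guards the factorization against round-off.

The fBm choice is a stand-in justified by its power-law mean-distance
property, not a mechanistic chromatin model: real traces need not be
Gaussian, and features such as loop extrusion, TAD boundaries or
compartmentalization are not emulated.  Passing parameter-recovery tests
therefore validates the *fitting machinery*, not any biological claim
about real chromosomes.

Default generator conditions: 21 regions at 1 Mb spacing over 1–21 Mb
(a ~21 Mb chromosome traced at one region per TAD-scale window), no
dropout, and for rendered scenes: 5 µm nuclei, two territories of 1.2 µm
radius per nucleus, voxels (0.1, 0.1, 0.2) µm (the 200 nm z-step of
typical stack acquisition), Gaussian spots of 0.12 µm sd.  Region dropout
is independent Bernoulli per region.  Rendered scenes place territory
spheres at the center distance that yields a requested marker overlap
fraction (lens-volume formula inverted by bisection) and shrink traces
into their territory, so the ground truth reflects the rendered, not the
raw, coordinates.

## Power-law fitting and its confidence intervals

`fit_power_law` estimates (a, s) by nonlinear least squares of
`d = a·g^s` over the valid entries of a mean distance matrix, initialized
from the log-log OLS line (which is also reported, since group
comparisons run on the log scale).  Two CI modes exist:

- default: Wald intervals from the curve-fit parameter covariance;
- when the trace population is supplied: a delete-group jackknife over
  traces (50 groups), refitting on each leave-group-out mean matrix.

The jackknife mode is the honest one for population matrices: all ~210
matrix entries are computed from the same traces and are strongly
correlated, so residual-based covariances understate the sampling
variance of (â, ŝ) severalfold.  Simulation at n = 1000 traces puts
jackknife CI coverage at ~93–97 % against ~40 % for the naive intervals.

Population matrices apply two hybridization-quality filters before
averaging: traces observing ≤ 6 of the 21 regions are dropped, and matrix
entries supported by ≤ 21 pair measurements are masked.

## Group comparison and difference maps

Two populations are compared by OLS on the pooled log-log data,
`Y = β₀ + β₁X + β₂G + β₃(X×G) + ε`: β₂ is the log step-size ratio and β₃
the exponent difference; their p-values test compaction and folding-path
differences.  Per-pair difference maps use a two-sided Wilcoxon rank-sum
test by default (Welch t-test selectable) with Benjamini–Hochberg
adjustment across pairs — a distribution-free default chosen because
spatial-distance distributions are right-skewed; this specific test choice
is a package decision, documented as such.

## Tracing and drop-out accounting

Foci are local maxima above threshold, refined to the intensity-weighted
centroid of the 3×3×3 neighborhood.  Chaining proceeds in genomic order
per territory from the lowest observed region, always linking to the
nearest focus of the next observed region; a missing interior region is
skipped (the link jumps to the next region present).  When the starting
region has several candidates the brightest seeds the chain; ties in
distance resolve to the first candidate (deterministic ordering).

Drop-out criteria are applied in a fixed precedence so every excluded
trace has exactly one reason: (1) duplicated region, (2) > 4 traces in
the nucleus, (3)/(4) > 2 traces per strain, (5) ambiguous strain
assignment.  Traces observing < 4 regions are removed *before* this
accounting as a minimum-length requirement and tallied separately — with
that ordering the five category counts plus the classified totals exactly
conserve the trace population, which `exclusion_accounting` enforces.

## Strain assignment

Each observed region's distance to a strain-marker mask is 0 if its
voxel lies inside the mask, else the minimum Euclidean distance to the
mask's 6-connected surface voxel centers (anisotropy respected; KD-tree
query).  Regions vote for the nearer strain with equal weight; exactly
equidistant regions abstain (counting them for both strains would let a
single degenerate region mask a genuine majority).  Equal vote totals —
including the degenerate case of two empty masks — yield an ambiguous
tie, which category (5) above removes.

## Clustering

Features are the vectorized upper-triangle pairwise distances per trace,
with configurable region exclusion (default: region 17, a low-yield
region) and missing entries imputed by the population mean of each pair
(neutral for distance-based neighbor search).  A k-nearest-neighbor graph
(k = 20) is reweighted by neighborhood Jaccard overlap (shared nearest
neighbors) and partitioned by Leiden modularity optimization at a given
resolution, seeded for determinism.  No scaling or PCA is applied before
the graph — with ≤ 210 features and distances on a common µm scale,
whitening would distort the conformation geometry; this is a package
choice where the toolchain convention is genuinely open.
`find_resolution_for_k` scans an ascending resolution grid for the
smallest value yielding a target cluster count (e.g. five), the guard
against over-clustering.

For pooled cross-strain clustering, the shorter strain's distances are
first size-adjusted: each pair's measured distance is divided by
`(g_B/g_A)^s` computed from the reference strain's fitted exponent, so
cluster structure reflects folding rather than chromosome length.

## Homolog analysis

Overlap ratio = shared marker voxels / (voxels A + voxels B), bounded by
0.5 for identical masks; ratios below 5 % count as non-overlapping (the
cutoff absorbs low-level cross-hybridization background), and 15 % is the
secondary "high overlap" threshold in summaries.  Stage-wise comparisons
use two-sample K-S tests on the ratios, with the sparse earliest stage
bin merged into the next (default 1–4 into 5–16) for sample size.

Inter-homolog matrices use nuclei with exactly two kept traces
(pre-replication).  A partner pair is discarded when its *minimum*
cross-trace region distance exceeds 6 µm — interpreted as "nowhere within
6 µm", which catches cross-nucleus mis-segmentation while keeping genuine
distant homologs; this reading of the partner filter is an interpretation
and is configurable.  Hybrid matrices orient rows to the maternal
homolog; homozygote matrices average both orderings and are exactly
symmetric.

## Segmentation and registration choices

Segmentation: low-quantile background subtraction, anisotropy-aware
Gaussian smoothing (σ in µm), Otsu binarization (overridable — the
upstream recipe leaves thresholds open, so they are exposed as config),
Euclidean distance transform with physical voxel spacing, watershed from
distance-transform maxima.  Territories are segmented identically with
the nuclear mask zeroing outside signal.  Interphase filtering uses voxel
count bounds plus sphericity `π^{1/3}(6V)^{2/3}/A` with the surface area
A from a marching-cubes mesh; the 0.6 default threshold is a package
choice, not an upstream constant.  Chromatic registration fits a full 3D
affine (closed-form least squares) to matched bead pairs — affine covers
shift, scale and shear with ≥ 4 non-coplanar beads — falling back to
translation-only with a warning on degenerate geometry.

Probe filters: Tm by nearest-neighbor thermodynamics (SantaLucia 1997
table, 50 mM Na⁺, 250 nM oligo, no formamide correction) — a
deterministic, documented surrogate for full probe-design pipelines;
GC and Tm bounds are closed intervals.  Uniqueness is exact k-mer
matching (default k = 18, both strands), deliberately conservative
compared with alignment-based screens.

## Problem sizes and determinism

The validation suite runs entirely on synthetic data: parameter-recovery
checks use 1000–2000 traces of 21 regions (seconds on one CPU), image
fixtures use 2-nucleus scenes of ~60×60×120 voxels.  All randomness flows
through explicit integer seeds (`numpy.random.default_rng`); identical
seeds give bit-identical traces, volumes and pipeline outputs, and the
pipeline driver stamps outputs with a config hash.

## Known limitations

- No optical PSF model, camera noise beyond Gaussian, drift between
  hybridization rounds, or sub-pixel multi-emitter fitting; spot
  localization is centroid refinement only.
- The generator's territories are spheres and its nuclei noise-free by
  default; segmentation robustness on real textured images is untested.
- Sister chromatids are not distinguished; the > 4-trace and
  > 2-per-strain rules only bound their impact.
- The χ² machinery assumes independent trace-to-cluster assignments;
  traces from one embryo are not independent, so p-values on real data
  are optimistic (Cramér's V is reported for exactly this reason).
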