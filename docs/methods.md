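# Methods

This note records the models, numerical choices and limitations behind
`conndiff`, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Networks

All analyses operate on symmetric r×r matrices over a fixed region atlas.
The atlas order defines matrix row/column order; edges are linearized
row-major over the strict upper triangle, 0-based, giving `M_G = r(r−1)/2`
edges. The diagonal is excluded everywhere and round-trips as missing.

### Functional connectivity (fMT, fPC)

Inputs are already-preprocessed region mean time series (T timepoints × r
regions); motion correction, filtering and nuisance regression are upstream
of this package. `fMT` is the pairwise Pearson correlation. `fPC` is the
partial correlation read off the precision matrix `P` of the sample
covariance (unbiased, T−1 denominator):

    r_ij = −P_ij / sqrt(P_ii · P_jj)

The square root in the denominator is the standard definition; without it
the quantity is not scale-free. Zero-variance regions are flagged and their
edges masked rather than failing the whole subject. Plain inversion
requires T − 1 ≥ r and non-degenerate data; an optional diagonal-loading
shrinkage (`cov + λI`, default λ = 0) handles marginally conditioned data,
which matters in practice when T is close to r (real cohorts sit around
r ≈ 82–84 regions and T ≈ 156–173 volumes). With λ = 0 a singular
covariance raises a conditioning error naming the covariance rank.

### Structural connectivity (DMC, DFA)

Given a voxel label image, an FA image and a non-negative local cost image,
the minimum-cost-path network is extracted with Dijkstra's algorithm
(`scipy.sparse.csgraph`) over the 26-connected voxel graph. The transition
cost of a step u→v is the physical center-to-center step length (mm) times
the mean of the two voxel costs — a trapezoidal line integral of the cost
field. 26-connectivity is used to reduce metrication error.

For a region pair (i, j), every voxel of region i seeds the search front at
cost 0 (travel within the source region is free) and `DMC(i, j)` is the
cheapest arrival over region j's voxels. This makes DMC near zero for
spatially adjacent regions, as expected of a travel-cost metric, and
produces a fully connected network whenever the grid is connected: every
pair receives a finite weight even with no direct anatomical connection,
because routes through intermediate tissue are admissible. Disconnected
pairs and voxel-less regions are masked as missing (with a warning), not
errors. Because the voxel graph is undirected the matrix is symmetric by
construction. For externally supplied *directed* cost/DFA matrices,
`symmetrize_directed` keeps the minimum of the two directed costs and the
companion DFA value of the winning direction (ties resolved in favour of
i→j with i < j).

`DFA(i, j)` is the sum of FA over the optimal path's voxels (endpoints
inclusive) divided by the straight-line endpoint distance in mm. Two
readings of "path length" are defensible; both are implemented
(`path_length="endpoint"` default, `"arc"` for the polyline arc length),
and the voxel-sum (rather than length-integrated) FA numerator is the
default. Determinism: Dijkstra's priority queue and the target-voxel argmin
both resolve ties in flat C-order, i.e. lexicographic voxel coordinates, so
repeated runs give identical paths.

The local cost field is a pluggable input. The default, `c(v) = 1 − FA(v)`
clipped to [10⁻³, 1], makes coherent white matter cheap to traverse while
keeping all costs strictly positive; any anisotropy-derived cost image can
be substituted.

## Edge statistics

Each edge is fitted by OLS: `weight ~ 1 + group + covariates`, group coded
0/1 so positive t means group 1 > group 0 (the convention places the group
of interest — elderly, patients — at 1). t and two-sided p come from the
group coefficient with df = n_used − (number of design columns). Edges
sharing a missingness pattern are fitted together (vectorized pseudo-
inverse); a rank-deficient design or zero residual variance masks the
affected edges with a warning rather than failing the run. With no
covariates the group t reduces exactly to the pooled two-sample t (verified
to 10⁻¹⁰ against `scipy.stats.ttest_ind`, and against `statsmodels` OLS
with covariates).

Missing-value policy: `exclude` (default) does per-edge listwise deletion;
`impute_group_mean` substitutes the edge's within-group mean. An edge
missing for an entire group stays masked under either policy. Group mean
networks use per-edge arithmetic means over non-missing values.

### Effective number of tests

The `M_G` edge tests are heavily dependent, so Bonferroni's denominator is
replaced by the eigenvalue-based effective number of independent tests

    M_eff = Σ_i f(λ_i),   f(λ) = 1[λ ≥ 1] + (λ − ⌊λ⌋)

over the eigenvalues of the between-edge Pearson correlation matrix,
computed on pooled subjects (both groups, raw weights — the simplest
reading; residualizing on covariates first would be a defensible variant).
With `M_G ≫ n` that matrix is rank-deficient; the spectrum is therefore
obtained from the n×n Gram matrix of the standardized edge rows, which
shares the non-zero eigenvalues — a contract requirement, since
materializing a 3486×3486 matrix of rank < 60 is both wasteful and
numerically noisy. Eigenvalues within 10⁻⁹ of an integer are snapped to it
before applying f: f jumps at the integers, and an eigensolver returning
2.9999999999999996 for an exact multiplicity-3 cluster must not land on the
wrong side. Constant edges make the correlation matrix undefined and raise
an error. Note f(λ) < 2 per nonzero eigenvalue, so M_eff ≤ min(M_G,
2·rank); M_eff ≤ M_G always. No correction is applied *across* network
kinds — the kinds under comparison are themselves strongly dependent, and
cross-metric correction is a study-level choice left to the user.

The adjusted threshold is `α_adj = α/M_eff` with α = 0.05 by default, and
the worm-plot scale is `s = log10(α)/log10(α_adj)`, chosen precisely so
that `−log10(α_adj)·s = −log10(α)` — one significance line for all kinds.

### Cluster shift tests

For each lobe-pair cluster, a one-sample two-sided t-test of the member
edges' t-statistics against zero measures a coordinated shift. Same-lobe
pairs (e.g. Fro/Fro) and cross-lobe pairs are treated alike, giving
g(g+1)/2 clusters for g lobes. This test treats edge t-statistics as
exchangeable draws; under dependence between edges its p-value is
approximate, which is why it is presented as a descriptive mid-level
screen, not a calibrated inference. Clusters with fewer than two usable
edges or zero variance are masked. Demographic summary comparisons use
Welch's t-test from printed summary statistics
(`scipy.stats.ttest_ind_from_stats`, Welch–Satterthwaite df) and Pearson's
χ² on 2×2 tables (continuity correction off by default, switchable).

## Visual encodings

Builders return plain data; matplotlib wrappers only draw it, so every
encoding is testable without image comparison.

* Worm plot: within each cluster, edges sorted ascending by t (stable,
  ties by edge index), spread evenly over a unit-width slot;
  `y = −log10(p)·sign(t)·s`; reference lines at ±(−log10 α). p = 0
  underflow is clipped to the smallest positive float with a warning.
* Bi-modal plots: 100 bins (1D) and 64×64 (2D) by default. Group-means
  mode colors each 2D bin by the group mix (pure blue = group 0, pure red
  = group 1, proportional blend through magenta) with opacity equal to
  count/max-count; t mode uses green. Bin counts per group always sum to
  that group's finite edge count.
* Connectogram: regions on a circle grouped contiguously by cluster
  (atlas order within cluster), angular spacing 360°/r. Chords are exactly
  the edges with p < α_adj; red for t > 0, blue for t < 0; opacity is an
  affine map of −log10(p) from [−log10(α_adj), max drawn] onto [0.3, 1.0];
  node saturation affine in significant-edge degree from 0.25 (degree 0)
  to 1.0 (max degree). The specific constants are fixed conventions; only
  monotonicity and the categorical color semantics are contractual.

## Synthetic cohorts

The generator produces the three input levels the pipeline consumes, fully
determined by one seed.

* Edge cohorts: `w_e = μ + β_e·group + γ·covariates + latent + ε` with
  Gaussian ε; β nonzero only on designated effect edges (β = effect_size ×
  noise SD, i.e. a standardized mean shift); an optional shared latent
  factor induces between-edge correlation for M_eff experiments. Null
  edges are independent Gaussians, so null p-values are exactly uniform —
  the right reference for type-I calibration.
* Time-series cohorts: zero-mean multivariate normal with block
  correlation (`rho_within` inside lobe clusters, `rho_between` across);
  group-1 effects are injected on the Fisher-z scale of the target
  correlations, keeping them in (−1, 1); both targets are checked for
  positive definiteness and rejected otherwise.
* Structural scenes: region blocks laid out on a small 3D grid (clusters
  along one axis, members along the other), background FA 0.25 plus
  smoothed noise, high-FA (0.8) tubes connecting designated region pairs,
  and group-1 ridge FA scaled by a configured factor — under the default
  cost 1 − FA, lowering ridge FA raises that pair's DMC and lowers DFA.

Defaults emulate a desk-scale study: 5 lobe clusters × 6 regions (r = 30,
M_G = 435), 30 subjects per group, T = 200 timepoints, structural grids of
a few thousand voxels. These sizes keep a full simulation–analysis cycle in
seconds while leaving enough edges and subjects for the correction and
calibration machinery to be exercised meaningfully. The calibration and
power runs in the test suite use 200 null cohorts and 100 effect replicates
at these sizes; the path-search oracle comparison uses exhaustive
enumeration on grids up to 4×4×1, where enumeration is tractable.

What the generator deliberately does not model: hemodynamics, scanner
noise spectra, head motion, DWI signal formation, registration error, and
realistic anatomical geometry. Passing tests therefore demonstrate the
correctness and calibration of the *statistical machinery* under its own
assumptions, not robustness to the artifacts of real acquisitions.

## Known limitations

* The local cost field is a simple FA transform by default; cost models
  fitted to diffusion data (e.g. orientation-aware costs) must be supplied
  as images.
* The cluster shift test inherits the dependence caveat above.
* M_eff is estimated from the sample correlation of edges; with very small
  n it is itself noisy, and the threshold inherits that noise.
* Partial correlation without shrinkage needs T − 1 ≥ r; shrinkage biases
  edges toward zero.
* The pipeline's figures target two groups; continuous predictors fit the
  same regression machinery but the dedicated group encodings (blue/red)
  do not apply.
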