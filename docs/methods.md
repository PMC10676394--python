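# Methods

## Scope and data model

All spatial computation happens on one shared regular grid. Rasters are
ESRI ASCII grids with cell-centre registration; a point belongs to the cell
`col = floor((lon − xll)/cellsize)` with rows flipped so row 0 is north,
and cells are half-open `[edge, edge + cellsize)` so edge points resolve
deterministically to the larger index. Layers are never resampled — inputs
must be pre-aligned, and alignment is checked to 1e-9 on all six grid
parameters. Cells equal to the nodata sentinel are masked, and a stack's
validity mask is the intersection of its layers' masks. For degree grids,
the area of a cell at latitude φ is `(cellsize · 111.32 km)² · cos φ`;
metre grids use the flat `cellsize²`.

Occurrence records are thinned to at most one point per grid cell (first in
input order wins) before modelling, the standard guard against spatial
pseudo-replication in presence-background modelling.

## The maximum-entropy model

The model of relative occurrence rate is the Gibbs distribution
`q(x) ∝ exp(λ·f(x))` over the fitting sample (presences ∪ background),
fitted by minimising

    L(λ) = −mean_presence[λ·f(x)] + log Z(λ) + Σ_j β_j |λ_j|.

Choices, and why:

- **Features**: linear + quadratic per continuous covariate, one indicator
  per category for categorical covariates, each min–max scaled to [0,1] on
  the training sample. Hinge/product/threshold features are deliberately
  omitted: the synthetic truths are smooth log-linear surfaces, and the
  smaller convex problem keeps every diagnostic exact and fast. This is a
  documented deviation from the Java MaxEnt defaults.
- **Regularization**: `β_j = reg_multiplier · sd(f_j over background) / √n_presences`
  with `reg_multiplier = 1.0`. The √n scaling mirrors standard
  maxent-style sample-size-dependent shrinkage. Constant features are
  dropped with a warning.
- **Optimizer**: cyclic coordinate descent. Each coordinate takes a
  proximal Newton step (gradient `E_q[f_j] − mean_presence[f_j]`, curvature
  `Var_q[f_j]`) soft-thresholded at `β_j/h_j`, backtracked by halving until
  the penalized objective does not increase; the objective is therefore
  non-increasing by construction. Convergence: a full cycle improving the
  penalized gain by < 1e-5 (1e-7 inside jackknife refits, where gains are
  differenced). Coordinate descent is not just an optimizer here — the
  improvement credited to each accepted update *defines* percent
  contribution, exactly as in the reference tool.
- **Background**: a uniform sample of valid cells, default 10,000 (all
  cells when fewer), seeded. Presences are appended to the background to
  form the normalizing sample, so `max_iter=0` yields the exact uniform
  `1/N` distribution.
- **Outputs**: raw `q`, cloglog `1 − exp(−e^H q)` (default), logistic
  `q e^H/(1 + q e^H)`, with `H` the entropy of the fitted distribution over
  the fitting sample. Training gain is `log N + mean_presence[λ·f] − log Z`.
- **Replicates**: each of the (default 10) replicates draws a fresh 75/25
  presence split and background; the reported surface is the cell-wise mean
  of the cloglog maps. The published protocol states both "25% testing" and
  "70% training"; 75/25 is used. AUC is the Mann–Whitney statistic over
  presence vs background scores divided by n₁n₂ (ties ½), with the usual
  quality gates (< 0.6 fails, < 0.7 poor, 0.7–0.9 good, > 0.9 excellent).

### Variable selection

1. **Zero-contribution iteration**: refit, drop layers contributing
   < 0.05% (a float-safe reading of "contribution rate of 0"), repeat until
   stable. The set shrinks monotonically, so termination is guaranteed.
   Note one honest caveat: with β ∝ sd/√n, both the penalty and the chance
   presence-background gradient of an uninformative feature scale as 1/√n,
   so a white-noise layer retains a small (≲0.3%) contribution in roughly
   half of replicates rather than always falling below ε. The tests assert
   the property that holds: noise layers rank last with < 1% contribution
   and are frequently dropped.
2. **Collinearity pruning**: pairwise Pearson r computed at the presence
   points (configurable to background or all cells); pairs with |r| > 0.8
   processed in decreasing |r| with the smaller-contribution member
   dropped. Processing order cannot change the outcome for transitive
   near-duplicate groups; ties break on contribution then name, so the
   result is independent of column order.
3. **Consensus main factors**: the intersection of the top-k (default 10)
   layers of the contribution, permutation-importance and jackknife
   `gain_with_only` rankings, ordered and summed by percent contribution.
   "Common to the three rankings" is an interpretation; k is exposed.

## Suitability zoning

Default class breaks are the fixed 0.1/0.3/0.6 thresholds (half-open
intervals, top class closed at 1.0); Fisher–Jenks natural breaks —
implemented as the exact dynamic program over prefix-sum SSEs, validated
against exhaustive partition enumeration — are available by flag. The DP
subsamples to 2,000 values above that size (O(kn²) cost); all tested sizes
are exact. Scenario comparison reports per-class areas both epochs, percent
change rates, and the full class-transition cell-count matrix. Change rates
recomputed from published *rounded* areas differ by a few tenths of a
percent from published rates (which used unrounded areas); rates here are
computed from exact areas.

## Fingerprint chemometrics

Peaks are local maxima above a prominence threshold; bounds are the
enclosing prominence bases, and area is the trapezoidal integral above a
linear baseline between the bounds. Retention-time drift is corrected by a
piecewise-linear warp through anchor peaks matched within a 0.5 min
window (samples matching < 2 anchors are left uncorrected with a warning).
Common peaks are greedy retention-time clusters (width ≤ 0.3 min by
default) containing exactly one peak from every sample — the strict 100%
prevalence convention of TCM fingerprint practice. The reference
fingerprint is the column-wise median (robust to a single aberrant sample;
mean available). Similarity is the included-angle cosine, which is
invariant to per-sample positive scaling — concentration differences do
not penalize similarity, composition differences do. Marker peaks are
selected by correlation-matrix PCA: retain components with eigenvalue ≥ 1,
select peaks with |loading| > 0.8 (loading = eigenvector·√eigenvalue) on
any retained component; "contribution degree" is read as absolute loading,
with the threshold configurable.

## Quality statistics

- **Mann–Whitney U**: statistic `min(U, n₁n₂ − U)` with ties counted ½;
  p exact (full enumeration of the null) when n₁n₂ ≤ 400 and untied,
  otherwise normal approximation with tie and continuity corrections;
  two-sided throughout, no multiplicity correction (matching the source
  protocol).
- **Stepwise OLS** follows the SPSS semantics: enter the candidate with the
  smallest partial-F p-value when < 0.05, then remove any included
  covariate with p > 0.10, iterate to a fixed point, refit by OLS.
  Because entry is tested per candidate without family-wise control, about
  `1 − 0.95^m` of pure-noise fits with m candidates admit a spurious
  covariate — a property of the method, preserved deliberately. Perfectly
  collinear candidates are skipped (rank check), so a duplicated column
  can never enter twice.
- **Spearman correlation** uses average-rank rho with the t approximation
  for p; ecological factors are clustered by average-linkage hierarchical
  clustering on distance 1 − |ρ|, cut at k = 3 by default.

## Fuzzy overlay

All layers entering the overlay are first min–max normalized to [0,1]
(over valid pre-mask cells; normalizing after masking is available by
flag). Operators: AND = min, OR = max, SUM = 1 − Π(1−v), PRODUCT = Πv,
GAMMA = SUM^γ·PRODUCT^(1−γ); default GAMMA with γ = 0.9, the common
ArcGIS practice where the source protocol says only "fuzzy superposition".
Suitability enters as one more [0,1] layer rather than a multiplier. All
22 indicators are treated as "higher = better"; a per-factor inversion
flag exists, since directionality is a domain judgement. The composed map
is masked over cells classified unsuitable. The operators satisfy
PRODUCT ≤ AND ≤ every input ≤ OR ≤ SUM cell-wise with GAMMA between
PRODUCT and SUM, which the tests assert; monotonicity in each input means
improving any indicator can never lower composed quality.

Factor subsets: *medicinal* = index components + effective compound groups
+ the 11 marker peak areas; *edible* = the five nutritional items;
*comprehensive* = all 22.

## The synthetic scene

`default_scene`: a 100×100 grid (cellsize 0.01°), 12 continuous layers
(Gaussian-filtered white noise, length scale 8 cells, standardized) of
which 2 pairs are planted collinear (`y = 0.95x + 0.1ε`, empirical
|r| ≈ 0.99), one 6-patch Voronoi categorical soil layer, and 200 presences
sampled without replacement ∝ exp(Σwx) with generating weights
{env03: 1.5, env04: −1.0, env05: 1.0} — the Gibbs form, so the maxent fit
is correctly specified. Chromatograms are sums of Gaussian peaks
(σ = 0.08 min on a 0–50 min gradient at 0.01 min sampling) from 20
templates, with log-normal per-sample area multipliers (unit median, CV
from the template), Gaussian retention jitter (default sd 0.05 min) and
baseline noise. Concentration tables are sparse linear functions of layer
values at the sample cells plus Gaussian noise. Every generator is a pure
function of (parameters, seed).

What the scene does *not* emulate: real geography or climate fields
(anisotropy, trends, units), sampling bias in occurrences, detector drift
or co-eluting peaks in chromatograms, or model misspecification (the
presence surface is exactly log-linear). Passing recovery tests therefore
demonstrates correctness of the inference machinery, not robustness to the
messiness of field data.

## Problem sizes and numerics

Tests and the acceptance script run the default scene (10,000 cells,
10 replicates), 60×60 scenes for replicate simulations, and n ≤ 12
instances for exhaustive oracles — sizes chosen so the whole suite
completes in well under a minute while leaving every statistical property
testable. Degenerate inputs fail loudly: constant layers cannot be
normalized (a 0.5 substitute is flag-gated), zero vectors have no cosine
similarity, empty test splits and out-of-range suitability values raise.

## Known limitations

- No hinge features or clamping; extrapolation beyond the training range
  of a covariate extends the quadratic response.
- The ASCII reader/writer handles single-band grids only; no GeoTIFF,
  reprojection, or datum support.
- Jenks breaks above 2,000 distinct values are computed on a subsample.
- Percent contribution inherits path-dependence from coordinate descent:
  correlated layers can trade credit, which is intrinsic to the
  definition rather than a defect.
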