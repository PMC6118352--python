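# Methods

## Model and estimators

The package treats each plasma-membrane sheet as a rectangular observation
window (default 1000 × 1000 nm) carrying a finite point pattern of gold
centroids. All statistics are conditional on the observed point counts; no
intensity model is fitted.

**Univariate K.** The estimator is K(r) = A n⁻² Σ_{i≠j} w_ij 1(d_ij ≤ r)
with the isotropic edge weight w_ij centred at the first point of each
ordered pair. The n⁻² normalization is kept deliberately (it is the form
this analysis tradition prints); it under-estimates K by a factor (n−1)/n
relative to the unbiased 1/(n(n−1)) form, which is available via
`unbiased=True` / `unbiased_k` in the config. Distance ties at exactly r
count as within (closed ball).

**Edge correction.** For a rectangle the interior fraction of a circle of
radius d centred at an interior point is computed by inclusion–exclusion:
each side at distance e < d removes an arc 2·arccos(e/d); when the circle
covers a corner (e_x² + e_y² < d²) the adjacent arcs overlap by
π/2 − arcsin(e_x/d) − arcsin(e_y/d), added back. Because a point inside the
window can never violate two opposite sides simultaneously, the pairwise
corner terms make the expansion exact for every radius; the test suite
verifies it against an independent angular-interval-intersection derivation
to machine precision. Weights become undefined only when the whole
circumference lies outside the window (radius beyond the farthest corner),
which raises an error; a warning fires when the grid exceeds
min(width, height)/4, where the correction's variance inflation becomes
material. The default 240 nm maximum on a 1000 nm sheet stays below that
bound.

**L transform and standardization.** L(r) − r = √(K(r)/π) − r. Envelopes are
pointwise nearest-rank upper quantiles over n_sim null simulations
(univariate null: CSR with the sheet's own n; bivariate null: toroidal
shifts of one channel). Standardization is pointwise *division* by the
envelope bound, chosen because it is the only transform that maps the
confidence bound itself to the constant 1, which is how the significance
line on standardized plots is defined; subtraction cannot do that. The bound
is clamped below at `envelope_floor` (10⁻⁶ nm) so division never blows up at
tiny radii where the empirical quantile can be ≈ 0 or negative; clamped
radii are carried as flags on standardized curves and reported in summaries.

**L_max.** The maximum of the standardized curve over the grid, ties broken
toward the smallest radius. Its argmax radius tracks (but does not equal)
the cluster dispersion: across σ ∈ {5, 10, 20, 40} nm the mean argmax rises
monotonically, sitting a few-fold above σ since L accumulates pairs out to
roughly the cluster diameter.

**Bivariate statistics.** K_bs sums over ordered (big → small) pairs with
the weight centred on the big point, K_sb symmetrically; K_biv is their
count-weighted combination (n_b + n_s)⁻¹[n_b K_sb + n_s K_bs], which is
invariant under exchanging the channels. The toroidal-shift null preserves
each channel's internal clustering while destroying cross-channel
association — the correct null for *association*, unlike joint CSR
re-simulation, which would also test marginal randomness. The shifted
channel is the small one by default (configurable). The LBI integrates the
standardized curve by the trapezoid rule over 10–110 nm on the 1 nm grid
(endpoints interpolated if they fall off-grid); higher-order quadrature is
unwarranted on a dense uniform grid.

**States.** Particles are grouped by single-linkage connected components at
a 15 nm linkage distance (pairs at exactly 15 nm connect); "within 15 nm"
chains naturally, so transitive linkage is the defensible reading, and a
clique-based rule would be ill-defined for chains. Components of size 1/2/≥3
are monomers/dimers/oligomers, fractions weighted by particle count. The
≥3 cut makes the three categories exhaustive; the stricter reading
(oligomer = size ≥ 4) is available via `oligomer_min_size=4`, in which case
size-3 components are reported as an explicit `unassigned` fraction so
fractions still sum to one.

**Group inference.** Conditions are summarized as mean ± SEM (SD/√k) over
sheets. The two-group curve test uses a residual bootstrap for replicated
curves: T = ∫(L̄_a − L̄_b)² dr with group means weighted by sheet point
counts (w_i = n_i/Σn; sheets with more particles estimate K with less
variance — equal weighting is a config option), residual curves pooled and
resampled with replacement into pseudo-groups of the original sizes, and
p = (1 + #{T* ≥ T_obs})/(n_boot + 1) (add-one convention, so p is never 0 at
finite n_boot). A one-group variant tests departure from CSR by
re-simulating CSR groups with the observed counts. Density (particles per
μm²) differences use classical one-way ANOVA via scipy.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| radius grid | 1…240, step 1 | nm | covers the nanodomain scales of interest on a 1000 nm sheet while keeping the edge correction well-behaved |
| envelope level | 0.99 univariate, 0.95 bivariate | — | the conventional significance lines for the two analyses |
| envelope n_sim | 1000 | — | quantile SE small relative to the bound at these levels |
| envelope floor | 10⁻⁶ | nm | pure numerical guard; flagged when active |
| LBI bounds | 10–110 | nm | the association window the integral summarizes |
| linkage | 15 | nm | inter-gold distance treated as "same cluster" given antibody + gold geometry |
| n_boot | 1000 | — | p-value granularity 1/1001 |
| pixel_size_nm | unset | nm/px | set when coordinates come from pixel-unit image exports |

## Synthetic data: what it does and does not emulate

Generators produce binomial CSR (uniform points at fixed n), a Neyman–Scott
cluster process (uniform parents; offspring displaced by isotropic Gaussian
σ or uniform-in-disc radius; toroidal wrapping so realized intensity matches
the specification without edge-density artifacts; optional CSR background),
bivariate patterns with a tunable fraction of shared cluster parents, and
independent Bernoulli thinning for labeling efficiency. Default scales
mirror the experimental design: 1000 × 1000 nm sheets, 15 sheets per
condition, 25 parents × 6 offspring = 150 points (~10²–10³ per μm²). No
per-condition gold counts are published for the original experiments, so
these defaults are order-of-magnitude choices, not measured values.

Not emulated: membrane physics (lipid chemistry, diffusion, binding
kinetics), antibody/gold steric exclusion (real gold particles cannot
overlap; generated points can), localization error, uneven staining, or
sheet-to-sheet heterogeneity beyond Poisson variation. Passing calibration
tests therefore demonstrates the statistics behave correctly on patterns
with known structure — not that any biological conclusion is reproduced.

## Calibration behavior and known limitations

* **Small-radius bias of L.** At radii where the expected pair count is ≪ 1
  (r ≲ 5 nm at ~150–300 points per μm²), K̂ is 0 for most sheets, so
  E[L(r) − r] ≈ −r rather than 0; the √ transform is also concave (Jensen).
  The mean L(r) − r over CSR sheets is therefore systematically negative at
  the first few radii — an estimator property, not an implementation error.
  The n⁻² normalization additionally biases L by ≈ −r/(2n) at large radii;
  with `unbiased=True` that component vanishes. Standardized curves are
  unaffected in practice because the envelope is built from the same
  estimator and inherits the same bias.
* **Pointwise envelopes.** The 99%/95% bounds are pointwise; scanning the
  whole grid for a peak (L_max) inflates the family-wise exceedance above
  the pointwise rate. Values of L_max slightly above 1 should be read
  accordingly; the bootstrap group test, not the envelope, is the formal
  comparison between conditions.
* **Labeling efficiency.** Gold counts under-report true molecule numbers by
  an unknown labeling efficiency, so state fractions describe *label*
  clustering; mapping to true stoichiometry is out of scope.
* **Rectangle-only windows.** Edge correction is analytic for rectangles;
  arbitrary polygonal windows are not supported.
* **Null-model reading.** For the bivariate statistic, independence — not
  spatial segregation — gives L_biv(r) − r ≈ 0; genuine segregation drives
  it negative. Interpretations that call 0 "segregation" conflate the two;
  the implementation follows standard theory.

## Problem sizes in the calibration suite

The shipped calibration suite uses 500 CSR sheets of 300 points for the
univariate CSR limit, 100 independent-channel and 30 co-clustered bivariate
sheets (150 + 150 points) with 1000-iteration envelopes, 200 bootstrap
repetitions at n_boot = 200 with 15 + 15 sheets of 100 points, and 15 sheets
per σ for the dispersion sweep — sizes at which Monte Carlo error is small
relative to the effects being checked while the whole suite runs in minutes
on one CPU.
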