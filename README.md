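# nanospat

Spatial point-pattern statistics for immunogold electron microscopy of
plasma-membrane sheets.

Transmission-EM imaging of ripped-off basal plasma-membrane (PM) sheets
labeled with antibody-conjugated gold nanoparticles yields, per sheet, the
2-D centroid coordinates of each gold particle inside a ~1 μm² window.
`nanospat` quantifies, from those coordinates alone:

* **nanoclustering** of a single labeled species (lipid probe, receptor),
* **co-localization** between two species labeled with 6 nm ("big") and
  2 nm ("small") gold,
* **oligomeric state** (monomer/dimer/oligomer populations),
* **gold density** as a proxy for surface expression level,

and compares conditions across replicate sheets (≥ 15 per condition) with
bootstrap and ANOVA tests. A synthetic-pattern generator (CSR, parent–
offspring nanoclusters, co-clustered bivariate channels, labeling-efficiency
thinning) makes every stage testable without microscope data.

## The statistics

For n particles x₁…xₙ in a window of area A, the univariate K-function is

    K(r) = A n⁻² Σ_{i≠j} w_ij 1(‖x_i − x_j‖ ≤ r),    r = 1…240 nm (1 nm steps)

where w_ij is the isotropic edge correction — the inverse of the fraction of
the circle centred at x_i with radius ‖x_i − x_j‖ lying inside the window,
computed analytically for the rectangle. The variance-stabilized transform

    L(r) − r = √(K(r)/π) − r

is 0 under complete spatial randomness (CSR) and positive at clustering
scales. Observed curves are standardized by pointwise division by the upper
99% bound of a Monte Carlo CSR envelope (conditioned on the sheet's n), so
the confidence bound maps to 1; the curve's peak, **L_max**, exceeds 1 when
nanoclustering is statistically significant, and the peak's radius estimates
the cluster length scale.

For two channels with counts n_b, n_s, the directed cross estimators
K_bs and K_sb (edge weight centred on the source point of each ordered pair)
combine into

    K_biv(r) = (n_b + n_s)⁻¹ [ n_b K_sb(r) + n_s K_bs(r) ],
    L_biv(r) − r = √(K_biv(r)/π) − r,

standardized against a 95% envelope built from random **toroidal shifts** of
one channel (which preserves each channel's internal clustering while
destroying cross-channel association). The **LBI** (L-bivariate integrated)
is the trapezoid integral of the standardized curve over 10–110 nm; values
above 100 — the integral of the significance line itself — indicate
co-localization.

Particles are assigned to monomer (component size 1), dimer (2) or oligomer
(≥ 3) populations via single-linkage components at a 15 nm linkage distance.
Group curve differences use a residual bootstrap for replicated curves
(point-count-weighted group means, 1000 resamples, add-one p-value); density
differences use one-way ANOVA.

## Worked example

Simulate 15 clustered sheets (25 cluster parents/μm², 6 offspring each,
σ = 10 nm) and analyze them end to end:

```sh
cat > run.yaml <<'YAML'
seed: 7
stages: [simulate, univariate, states, report]
analysis: {n_envelope: 1000}
scenario:
  kind: clustered
  sheets: 15
  condition: treated
  cluster: {parents: 25, offspring: 6, sigma: 10.0}
YAML
nanospat run --config run.yaml --out out
```

Pooling `out/univariate_summary.json` and `out/states.json` gives

    L_max mean±SEM: 13.24 ± 0.23     (≫ 1: strong nanoclustering)
    argmax radius mean: 36.1 nm      (reflects the ~10 nm cluster dispersion)
    density mean: 150 per um2
    monomer 0.133  dimer 0.074  oligomer 0.793

Every sheet's L_max is far above the significance line at 1, the peak radius
sits a few-fold above the generating σ (the L statistic peaks near the
cluster diameter scale), and most particles fall in ≥3-particle components —
exactly what a strongly clustered pattern at 150 particles/μm² should show.

The bivariate analogue via the API:

```python
import numpy as np, nanospat as ns

spec = ns.BivariateSpec(shared_fraction=1.0)   # both channels share parents
scores = []
for s in range(15):
    bt = ns.gen_bivariate(spec, seed=100 + s)
    l = ns.l_biv_transform(ns.k_bivariate(bt.pattern).k_biv)
    env = ns.bivariate_envelope(bt.pattern, n_sim=1000, seed=200 + s)
    scores.append(ns.lbi(ns.standardize(l, env)).lbi)
print(np.mean(scores))
```

prints an LBI of `464.8 ± 12.7` (mean ± SEM) — far above the 100 threshold,
as expected for fully co-clustered channels; independent channels give mean
LBI near 0.

`nanospat --help` lists the remaining subcommands (`simulate`, `univariate`,
`bivariate`, `states`, `compare`).

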