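# Methods

## Study design emulated

The package models a climatic-chamber factorial experiment on reused broiler
litter: bedding substrate (wood shavings, max 4 reuse cycles; coffee husks,
max 6) × air temperature (25, 30, 35, 40 °C) × reuse cycle, three replicate
facilities per cell. Each litter sample carries moisture (% dry basis), pH,
total nitrogen and ammoniacal nitrogen (g kg⁻¹), measured before ("initial")
and after ("treated") the 24-h thermal exposure; initial samples predate the
treatment and are therefore temperature-free.

## Synthetic-data generator

Real chamber data are not publicly deposited. The generator therefore treats
the study's published per-cycle regression equations (one per bed type ×
variable × condition, linear or quadratic in the cycle C) as cell means and
adds independent Gaussian noise with sd = `noise_scale` × the equation's
standard error of estimate (SEE). SEE is the only dispersion the source
analysis reports, so a Gaussian at SEE scale is the least-committal noise
model; `noise_scale = 1` is the default, 0 reproduces the mean structure
exactly. After noise, moisture is clipped to [0, 100] %, pH to [0, 14],
total N to ≥ 0 and ammoniacal N to [0, total N]; clip events are counted in
`df.attrs["n_clipped"]` rather than silently absorbed. Default replication
is 3, matching the study.

Response surfaces (NH₃ generation in g kg⁻¹; SMDAE emission flux) are drawn
from the published models with either a constant noise sd or a
heteroscedastic sd equal to a fraction of each cell mean; the recovery
studies use 5% of the cell mean.

What the generator does **not** emulate: spatial within-house compositing
(each replicate is one composite sample), any between-cycle litter dynamics,
correlated errors between variables, or non-Gaussian residuals. Passing
tests therefore demonstrate correctness of the statistical machinery under
the stated mean/noise model, not fidelity to unpublished raw data.

## Speciation and flux

The generation potential is the dissolved NH₃-N concentration
1000·TAN / {K_f·10⁻ᵖᴴ/K_d0 + MC·(1 + 10⁻ᵖᴴ/K_d0)/ρ_H₂O} (µg L⁻¹), with TAN
in µg g⁻¹ dry basis (sample tables store g kg⁻¹; the ×1000 bridge is the
exported constant `G_PER_KG_TO_UG_PER_G`). K_f (L kg⁻¹) and K_d0
(dimensionless) are litter-specific and not derivable here; the defaults
(K_f = 1, K_d0 = 10⁻⁹, the ambient-temperature order of magnitude of the
ammonium dissociation constant) are placeholders that users must replace
with measured values. K_d0 is temperature-dependent in principle; it is
exposed as configuration rather than modelled. The function is homogeneous
of degree 1 in TAN and monotone non-decreasing in pH; both are property-
tested.

The SMDAE flux is captured NH₃ mass / (sponge area × exposure time),
computed in g m⁻² s⁻¹ with an mg switch; geometry defaults to the standard
device (20 cm diameter sponge, 24 h exposure). Only the lower capture
sponge enters the computation; the upper sponge is a shield against ambient
contamination.

## Regression layers

**Interaction screen.** Fixed-effects two-way ANOVA (cycle, temperature,
interaction) on the balanced factorial, at least two replicates per cell.
The additive response surfaces used everywhere else are justified by this
screen coming out negative.

**Univariate cycle fits.** OLS with intercept on C (and C² when requested);
slope terms with p > α are removed highest degree first. A constant response
collapses to the intercept with R² defined as 0.

**Backward elimination.** Candidate pool 1, T, T², T³, C, C², C³ (no T×C
cross term, consistent with the negative interaction screen). At each step
the eligible term with the largest partial t/F p-value above α (default
0.05) is removed; ties go to the higher-degree term, then to the later
canonical position. The intercept competes for removal like any other term;
once removed the model passes through the origin.

*Eligibility is hierarchical*: only the highest remaining power of each
variable (plus the intercept) is testable at a given step. Raw powers of T
on a four-level grid spanning 25–40 °C are nearly collinear
(corr(T, T³) ≈ 0.996), and unrestricted max-p removal lets a spurious higher
power displace the linear term, yielding unstable, uninterpretable
coefficients; hierarchical degree-testing removes that pathology and is the
classical order for polynomial response surfaces. An unrestricted variant
remains available (`strategy="max_p"`). A consequence of hierarchy is that
a retained lower power may itself be non-significant while shielded by its
significant higher power; the significance guarantee at termination applies
to testable terms.

*Degenerate fits*: when the current model reproduces the data to numerical
precision (SSE ≤ 10⁻¹² × Σy²), t statistics are 0/0 noise; terms are then
judged by whether the fit stays numerically perfect without them, and exact
redundancies are pruned wherever they sit in the hierarchy. Noiseless data
generated from any candidate-subset model — hierarchical or not — are
recovered exactly.

*Conventions*: SEE = √(SSE/(n−k)) with k the number of estimated
coefficients; without an intercept R² is computed against the uncorrected
total sum of squares (the standard through-origin convention). An empty
final model returns the null model with a warning rather than raising.

## Adequacy engine

For each of `n_sim` simulations (default 1000, the study's count) the data
are randomly split into a generation subset of ⌊n/2⌋ rows and a test subset
of the remainder; backward elimination is re-run on the generation subset by
default (a `fixed_terms` mode refits a frozen form instead), and the test
subset is scored by:

- **QMEP** = mean((o−p)²), partitioned into mean deviation (ō−p̄)²,
  systematic deviation (s_p − r·s_o)² and random error (1−r²)·s_o². With
  population (÷n) moments the three components sum to QMEP as an algebraic
  identity, which the suite checks to 10⁻¹⁰ relative; sample (÷(n−1))
  moments would break exactness.
- **Lin's CCC** = 2·r·s_o·s_p/(s_o² + s_p² + (ō−p̄)²), decomposed as ρ·C_b
  with ρ the Pearson correlation and C_b = 2/(v + 1/v + u²),
  v = s_o/s_p, u = (ō−p̄)/√(s_o·s_p) — the numerically stable form that
  makes CCC = ρ·C_b hold to rounding error.
- **R²**, by default the squared Pearson correlation between observed and
  predicted (an SSE-based alternative is switchable).

The report averages each statistic across simulations; partition components
are averaged as percentages of each split's QMEP, so they sum to 100.
Splits with zero test-set variance are counted as degenerate and excluded
from the correlation-based averages; splits on which fitting fails are
logged, skipped and counted, and more than 10% failures aborts the run.
All randomness flows from a single integer seed.

## Parameter recovery protocol

Each published response model is used as generating truth on its own grid
(3 replicates, noise sd = 5% of the cell mean); backward elimination is
re-run on 200 independently seeded datasets. The linear temperature
coefficient is summarized over the replications whose retained terms are
exactly the published form {T, C, C²}: when a spurious higher T power
survives instead, the collinear linear coefficient is not comparable to the
printed value. Known limitation: for the weakest temperature signal (the
wood-shavings generation model, full-model t ≈ 2.4) conditioning on
retention inflates the recovered coefficient slightly (a winner's-curse
effect of a few percent, seed-dependent); the stronger-signal models recover
essentially unbiased. Intercept retention in these runs exceeds the nominal
5% type-I rate by a couple of points, driven by the same runs in which a
spurious T²/T³ survives and the intercept patches curvature.

## Pipeline

`run_pipeline` chains simulate → responses → potential → flux → fit →
validate, writing CSV/JSON artifacts plus a `run.log` that echoes the
configuration and the per-stage integer seeds derived from the master seed
(via `numpy.random.SeedSequence`), so any stage can be re-run in isolation.
Output uses '.' as the decimal separator regardless of locale.

## Problem sizes

Defaults mirror the study: full factorial grids, 3 replicates, 1000
cross-validation splits, 200 recovery replications. The test suite uses the
same grids with fewer cross-validation splits (tens) where the check is a
contract (determinism, config propagation) rather than a distributional
statement; distributional checks keep their stated sizes (2000 ANOVA
type-I simulations, 500 oracle datasets, 200 recovery replications per
model).
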