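# Methods

This note records the models implemented in `synscreen`, the assumptions
behind them, the defaults and why they were chosen, and what the
synthetic-data generators do and do not emulate.

## Plate model and normalization

A plate is a long-format table of wells with roles `sample`, `neg_ctrl`
(vehicle), `pos_ctrl` (a cytotoxic control such as a proteasome
inhibitor), and `blank` (cell-free). The checkerboard block occupies the
upper-left grid, with the vehicle well at its (1,1) corner carrying the
`neg_ctrl` role; single-agent wells are `sample` wells with one dose at
zero. Raw optical density is normalized to percent-of-vehicle viability

    V = 100 · (OD − blank_mean) / (vehicle_mean − blank_mean)

clipped below at 0. Values above 100 (apparent stimulation) are
**retained**: clipping them would systematically bias excess scores
toward synergy. Blank wells are optional (blank mean defaults to 0). The
vehicle cell is set to 100 exactly. Missing sample wells are never
imputed — imputation could fabricate synergy evidence — so an incomplete
block raises an error and is excluded from ranking, and a plate that
fails QC is excluded from a compound's cross-cell-line average rather
than zero-filled (normalization of a failed plate requires an explicit
`force=True`).

The Z′ factor uses sample standard deviations (ddof = 1), computed on
values shifted by the first element so that constant control vectors give
exactly Z′ = 1. Thresholds are configuration keys (`z_min_primary = 0.6`
for 96-well primary screens, `z_min_secondary = 0.5` for 384-well
secondary screens) because both conventions are in routine use.

## Synergy scores

Both scores work on the percent-viability scale, negative = synergy:

* ExcessHSA per combination well is observed viability minus the
  *minimum* (most effective) single-agent viability at the well's
  marginal doses — the highest-single-agent reference.
* Bliss excess is observed viability minus the independence expectation
  V_a·V_b/100 of the marginal survival fractions.

The matrix statistic is the **sum** over combination wells, not the
mean; consequently 10×10 matrices produce numerically larger sums than
6×6 matrices at the same per-well effect, and the classification
thresholds (±20, closed interval additive) are configurable per design.
Single-agent wells do not contribute to the sums; this choice is
recorded in output metadata. Ranking averages a compound's sums over
its QC-passing cell lines and breaks ties lexicographically by compound
name, so regression tests are deterministic.

Note an intrinsic property of the two references: for a Bliss-null
surface with active single agents, the HSA reference lies above the
Bliss expectation, so ExcessHSA is negative even with no interaction.
ExcessHSA therefore only separates interaction classes cleanly when
single-agent effects at screening doses are modest — see the library
generator below.

## Median-effect model and combination index

Single agents follow fa/fu = (D/Dm)^m. Fitting is unweighted OLS on the
linearized plot log10(fa/fu) = m·log10 D − m·log10 Dm, the classical
method; weighted variants are out of scope. Points with fa outside
(ε, 1−ε), ε = 0.005, are excluded and counted (mirroring common
practice in CI software); fits with all usable fa on one side of 0.5
carry an extrapolation warning. The fitted curve satisfies fa(Dm) = 0.5
identically.

CI is computed per combination well (the screen is a checkerboard, not
a constant-ratio series): CI = d₁/Dx₁ + d₂/Dx₂ with
Dx_i = Dm_i·(fa/(1−fa))^(1/m_i). The two-term mutually-exclusive form is
the default; the mutually-nonexclusive form (adding d₁d₂/Dx₁Dx₂) is
available behind `ci_form`. A zero dose degenerates to the one-term
single-agent form, which is exactly 1 when the dose equals Dx at the
observed effect.

The four-parameter logistic reports the relative (inflection) IC50, the
GraphPad-style convention, recorded in output metadata; a rising
dose-response is flagged with a hill-sign warning rather than silently
fitted.

## TGI and IRS

TGI aligns the two arms on their first and last *shared* measurement
days (configurable only insofar as the input schedule defines it);
means at each day use the animals still measured, and animals removed
early are excluded from the final mean with a logged count. The formula
100·[1 − ΔV_t/ΔV_c] is scale-invariant, so volume units cancel.
Responder (> 60) and regression (> 100) thresholds are strict
inequalities. A control arm with zero net growth makes TGI undefined and
raises an error. No caliper-to-volume conversion is applied; an optional
helper implementing the V = L·W²/2 convention is provided but not used
by the pipeline.

IRS uses the printed percentage bins (0% → 0, 1–10 → 1, 11–50 → 2,
51–80 → 3, 81–100 → 4); fractional percentages in (0, 1) round up to
category 1, a documented edge case since the bins are stated on
integers. The product with intensity (0–3) is surjective onto
{0, 1, 2, 3, 4, 6, 8, 9, 12}.

## Synthetic data: what it emulates, and what it does not

**Checkerboards.** Dose grids are serial dilutions (default: 5 points,
1:5 from 20 μM, i.e. 20 → 0.032 μM; the 10×10 design uses 9 points 1:3
from 20 μM, 20 → ~0.003 μM) plus a vehicle level. Single-agent effects
follow the median-effect equation; combination inhibition is the Bliss
expectation plus an offset δ applied on the inhibition-fraction scale
*before* conversion to viability, so Bliss truth is exact by
construction (δ > 0 synergy, δ < 0 antagonism). Offsets are clipped to
[0, 1]; if more than 5% of wells clip, the truth object carries a
warning flag so tests can avoid saturated regimes. Noise is
multiplicative lognormal on OD (σ default 0.03), plate-reader-like:
positive signals, scale-free. Controls: positive-control wells at a 2%
surviving fraction, extra vehicle wells, and blanks. Same seed ⇒
byte-identical output.

**Library defaults.** `DEFAULT_LIBRARY_SPEC` places both single-agent
median-effect doses at 200 μM, ten-fold above the top screening dose, so
single agents inhibit ≤ ~9% anywhere on the grid. Under these conditions
a δ = 0 pair scores ExcessHSA ≈ −16 (additive) and interaction class is
driven by δ alone; with potent single agents the HSA/Bliss reference gap
(previous section) would label non-interacting pairs synergistic. This
emulates a screen read out for interaction rather than single-agent
potency.

**Xenografts.** V(t) = V₀·exp(k(1−e)t) with lognormal measurement noise;
e is the per-arm drug effect (0 none, 1 stasis, > 1 regression). Truth
TGI comes from the closed form on noiseless means. Defaults: V₀ = 100
mm³, k = 0.1/day, 8 animals/arm, twice-weekly measurements over 21 days.

**Not emulated:** plate edge effects, pharmacokinetics, resistance
dynamics, inter-animal baseline heterogeneity beyond measurement noise,
and real compound identities. Passing tests therefore demonstrate
correctness of the arithmetic and estimators under the stated noise
model, not robustness to the systematic artifacts of real screens.

## Numerical choices and study sizes

* Dose-response recovery studies use 200 seeds; the median-effect study
  uses a 9-point 1:2 series from 20 μM bracketing Dm = 2.5 μM with 1%
  multiplicative noise on the unaffected fraction. Dose placement
  matters: a 1:3 series from 20 μM leaves four doses in the zero-effect
  tail where signal noise dominates the log-odds, roughly tripling the
  median Dm error; bracketing the median-effect dose is what a
  practitioner fitting Dm would do.
* Bliss-null noise calibration uses 60 replicate plates and checks the
  grand mean of per-well excess against 3·SE of the per-plate means.
* TGI recovery uses 200 simulated two-arm studies and checks the mean
  estimate against the closed-form truth within 3·SE.
* The demo library and end-to-end ranking tests use 6–20 compounds and
  1–2 cell lines; the full 162 × 4 design (648 plates, 16,200
  combination pairs) is instantiated where the screen's design
  arithmetic itself is the quantity of interest.
* Floats in plate CSVs are written in shortest round-trip form and read
  back with round-trip precision, so a write–read cycle is
  bit-identical.

## Known limitations

* ExcessHSA classification thresholds (±20) are calibrated for 6×6
  sums; reusing them for 10×10 matrices is conservative about
  antagonism and liberal about synergy (sums scale with well count).
  The config exposes them; no rescaling is applied automatically.
* CI per-well on a checkerboard mixes combination ratios; Fa–CI curves
  are therefore scatter, not a function of fa alone.
* The median-effect fit is undefined when all usable fa sit at exactly
  one dose or the slope is zero; these raise errors rather than
  returning degenerate parameters.
* QC-failed plates are dropped, not corrected; there is no edge-effect
  or spatial normalization.
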