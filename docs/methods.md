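# Methods

## Cofermentation model

The growth model is unstructured: biomass X (g/L) is one lumped pool, and
the culture ferments glucose, xylose and arabinose simultaneously. The
specific growth rate contributed by sugar *i* is

    mu_i = mu_max_i * S_i/(K_S_i + S_i) * rep_i(S_glc)
           * 1/(1 + L/K_L) * max(0, 1 - P/P_max)^n_P

with

* **Monod saturation** per sugar (`mu_max_i` in 1/h, `K_S_i` in g/L);
* **catabolite repression** of pentose uptake by glucose,
  `rep_glc = 1`, `rep_xyl = rep_ara = K_rep/(K_rep + S_glc)`. The term is
  smooth rather than a hard diauxic switch because partially overlapping
  sugar consumption is observed in practice (strains can leave both
  glucose and pentose residuals); `K_rep -> 0` recovers strictly
  sequential consumption;
* **lignin inhibition**, hyperbolic in the (non-consumed) alkali-lignin
  level L with constant `K_L` (g/L);
* **product inhibition**, a power law that stops growth entirely at
  lactate `P = P_max` (exponent `n_P`).

Balances: `dX/dt = mu X` with `mu = sum_i mu_i`;
`dS_i/dt = -(mu_i/Y_XS_i) X`; Luedeking–Piret lactate formation
`dP/dt = (sum_i alpha_i mu_i) X + beta_LP X`; `dL/dt = 0`.

Each inhibition factor has an independent switch in `MonodParams`, so
alternative rate-law families can be compared without touching the
integrator. The exact functional forms are a modelling choice from the
standard unstructured-model repertoire for lactic acid cofermentation;
they are deliberately provisional, and that is why they are switchable.

Assumptions and limits: no pH/base-titration dynamics, no temperature
dependence, no structured or segregated biomass, lignin is a pure
inhibitor without a mass balance (its removal is analysed separately from
UV spectra), and the non-growth-associated lactate term keeps producing
as long as biomass is present even after sugar exhaustion — harmless for
fermentation-time bookkeeping but not meaningful far beyond it.

### Integration

`scipy.integrate.odeint` (LSODA) with `rtol = 1e-6`, `atol = 1e-8`
(recorded in every `Trajectory`). The right-hand side clips negative
concentrations before evaluating rates, so an overshoot of order `atol`
at sugar exhaustion cannot generate spurious fluxes; output states are
floored at 0 and the number of floored values is reported
(`clip_events`). Equivalence with a fixed-step RK4 oracle at dt = 1e-3 h
is held to a relative error below 1e-3 in the test suite.

### Fermentation time

`FT` defaults to the first grid time at which total residual sugar drops
below 0.5 g/L (fast runs drive sugars to ~0), falling back to the last
grid time. A fixed-harvest rule (`rule="harvest"`) is provided because
slow runs are stopped at a set time (typically 48 h) with sugar left
over; which convention a given published FT value reflects is not always
decidable, hence the configurable stop rule.

## Genetic-algorithm estimation

The objective is the weighted pooled SSE between observed and simulated
series at the observed time points, skipping missing values. Default
weights are `1/range(variable)^2`, so ~5 g/L biomass and ~65 g/L lactate
contribute comparably; a failed simulation scores +inf (infeasible).

The optimizer is a bounded real-coded GA: tournament selection (size 3),
BLX-0.5 blend crossover (probability 0.9), Gaussian mutation (probability
0.1 per gene, sigma = 0.1 of the bound range, clipped to bounds), and
2-elite preservation; defaults pop 80 / 200 generations, all overridable.
All randomness flows from one integer seed, and identical config + seed
gives a bit-identical result. Elitism makes the best-objective history
non-increasing, which is asserted on every run.

An optional local polish (bounded Nelder–Mead simplex on the GA winner)
is off by default. It matters for one specific situation: on noise-free
data the SSE valley coupling `mu_max` and `K_S` is long, curved and
shallow, and the GA alone parks anywhere along it depending on the seed
(observed spread on `mu_max`: ~0–35% across seeds, while the yield is
pinned within <1%). The noise-free recovery experiment therefore runs
with `polish=True`, which lands on the exact least-squares optimum for
any seed; the noisy recovery experiment uses the plain GA and is judged
on medians over 10 seeds. `K_S` is reported but carries no recovery
bound: at near-saturating sugar it is weakly identifiable, a documented
property of Monod kinetics, not of the optimizer.

Fitting is per-run; a joint fit across lignin levels can be composed by
summing objectives but is not the default.

## Fit-quality statistics

All paired state variables are pooled into one observed vector and one
model vector. `sigma` is the RMSE `sqrt(sum (obs-model)^2 / n)` in
concentration units — so its magnitude tracks the concentration scale of
the run (tens of g/L for artificial medium, ~1–2 g/L for dilute
hydrolysates). `R^2 = 1 - SS_res/SS_tot` about the observed mean. The
model-equality test is a single-factor ANOVA with exactly two groups
(observed values, model values), df = (1, 2n−2); the model is accepted at
95% when `F < F_critical = F^-1(0.95; 1, 2n-2)`, equivalently p > 0.05.
For two groups F equals the squared pooled-variance t statistic, which
the tests assert against an independent implementation. Degenerate
zero-within-variance inputs yield F = +inf (p = 0) and are flagged.

## Plate screening

The honeycomb plate (10×10) follows the screening scheme: columns 1–3
medium blanks (one column per sugar medium, two wells per lignin level),
column 4 water blank, columns 5–10 growth wells — two columns per sugar
medium (60 g/L glucose; 60 g/L xylose; 40 g/L glucose + 20 g/L xylose)
and two rows per lignin level (0.0–0.8 g/L), i.e. four replicate wells
per condition. Blank correction subtracts the mean of the two matching
medium-blank wells time point by time point; negative corrected values
are floored at 0 and counted.

Growth curves are fitted in log-growth form `y = ln(OD/OD0)` with OD0 the
mean of the first two corrected points (floored at 1e-3), using the
modified (Zwietering-style) logistic
`y = A/(1 + exp(4 mu_max/A (lam - t) + 2))` whose parameters are exactly
the reported quantities: amplitude A, maximum specific growth rate
mu_max, lag time lam. Two numerical choices beyond that parameterization:

* a bounded nuisance **baseline offset** is co-estimated, absorbing the
  error of the OD0 estimate (under additive OD noise the two-point OD0 is
  noisy, and without the offset the bias lands mostly in lam);
* residuals are **weighted by OD** (sqrt weights in log space), which is
  least squares under the instrument's additive-OD noise; unweighted log
  residuals let the noisiest low-OD points dominate.

With both, recovery on noise-free curves is exact and noisy recovery of
(A, mu_max, lam) reaches ~1–4% median error per condition. Fits are
per-well, aggregated per condition by median (robust to one bad well in
four). Wells whose corrected OD never exceeds 0.05 are flagged "no
growth" (A = 0, mu_max = 0, lam = last time).

beta, the per-condition composite growth parameter, defaults to the
fitted mu_max (alternatives `A*mu_max` and `A` are selectable and the
choice is recorded in outputs; the composite definition is a convention
inherited from screening practice, and every candidate declines with
lignin). The beta-vs-lignin relation is fitted by OLS on explicitly
included points — exclusion is user input, mirroring how visually
flagged outliers are dropped in practice — and the x-intercept
`-intercept/slope` extrapolates the lignin tolerance when the slope is
negative; otherwise the tolerance is flagged non-finite.

## Performance metrics

`P = C_LA,max / FT` (g/L/h). Substrate yields divide by the total
*supplied* sugar (sum of per-sugar maxima) and the biomass yield uses the
biomass maximum, not the baseline-subtracted increment — the conventions
that exactly reproduce the fully-consumed reference rows (e.g.
7.78/77.76 = 0.1000, whereas ΔBM would give 0.0995). For runs with
residual sugar a consumed-sugar denominator `sum(max - min)` is arguably
more meaningful, and both variants are always reported; the
partially-consuming strain rows of the source table are internally
inconsistent with any single convention, so the package reports rather
than resolves. Optical purity is a pass-through measured upstream by
chiral analysis. `TCC = 1.66e12 * BM` converts biomass to total cell
count per the turbidimetry calibration, with an exact inverse.

## Decolorization

Uptake of alkali-lignin, ferulic acid and vanillin is quantified from UV
spectra (250–400 nm): the timed sample is linearly interpolated onto the
blank's wavelength grid; the anchor wavelength is the blank's absorbance
maximum inside a compound band (defaults AL 270–290 nm, FA 300–330 nm,
VAN 290–320 nm — typical aromatic absorption regions, fully
configurable); fractional decolorization is `1 - A_sample/A_blank` at the
anchor, plus a band-integrated (trapezoid) variant since a single-
wavelength and a whole-band comparison can differ for asymmetric uptake.
Negative fractions (apparent release, e.g. turbidity carry-over) are
reported and flagged, never clipped. Blanks at or below a 1e-3 AU noise
floor make the fraction undefined and raise.

## Synthetic data

The generator stands in for the study's raw spreadsheets with known
ground truth.

* **Fermentations**: simulated from three strain presets at the study's
  scales — artificial-medium sugars 46/21/10.6 g/L (glc/xyl/ara;
  hydrolysate preset 7/2.5/0.5), inoculum 0.03 g/L, lignin levels
  {0, 0.625, 1.25, 2.5, 3.75} g/L, 2 h sampling. The fast preset was
  calibrated by forward simulation to the published fast-strain run
  characteristics (FT 26 h, X_max ≈ 6.1, lactate ≈ 69 g/L at zero
  lignin); the third preset stalls by product inhibition near 47 g/L
  lactate leaving pentose residuals at 48 h. Presets are
  order-of-magnitude archetypes, not fitted constants. Noise: 2%
  multiplicative lognormal plus an additive N(0, 0.05 g/L) floor,
  clipped at 0 — typical HPLC precision.
* **Plates**: wells per the layout above; growth wells carry cell
  turbidity `OD0 * exp(y(t))` (OD0 = 0.06) on a drifting medium baseline
  (0.08 + 0.001 t + 0.05 L), with additive N(0, 0.01 AU) noise. True
  mu_max declines linearly to zero at a programmed per-medium lignin
  tolerance (glc 1.20, xyl 0.90, mix 1.05 g/L); lag grows with lignin.
  The run lasts 72 h at the turbidimeter's 15-min interval so that even
  the slowest near-tolerance condition reaches stationary phase — the
  logistic fit requires curves spanning lag and plateau.
* **Spectra**: Gaussian compound peaks (AL 280/18 nm, FA 316/14, VAN
  307/13; heights ~1 AU) over a 0.003 AU medium baseline; timed samples
  attenuate the compound peak by programmed fractions (0.2 at 2.5 h, 0.5
  at 5 h). Noise defaults to 0 (spectrophotometers average internally);
  an additive noise knob exists.

Every artifact embeds its `ScenarioSpec` (seed included) for exact
regeneration. What the generator does **not** emulate: sampling-time
jitter, systematic HPLC drift or carry-over, well-position (edge)
effects, condensation artifacts, non-Gaussian spectral baselines, and
any mismatch between the assumed and the true growth law — passing
recovery tests therefore demonstrates correctness of the estimation
machinery under the stated noise model, not robustness to structural
model error in real data.

## Problem sizes

The recovery experiments use a glucose-only series (33 points over 16 h)
with truth mu_max 0.5/h, K_S 2 g/L, yield 0.08 — chosen so all three
parameters are structurally identifiable (sub-saturating S0 = 20 g/L and
a resolved depletion tail). The GA uses pop 60 × 80 generations
(noise-free) and pop 50 × 60 × 10 seeds (noisy); the screening analysis
fits all 60 growth wells of one plate; simulator invariants are checked
on 100 random parameter draws within plausible bioprocess ranges.

## Known limitations

* The rate-law forms (especially product inhibition) are provisional;
  only their family, not their constants, is claimed.
* K_S is practically non-identifiable from near-saturating batch data;
  fits report it but no accuracy is promised.
* The ANOVA equality test pools all state variables; with variables on
  very different scales the pooled test is dominated by the largest
  scale (the same is true of sigma, by construction).
* The beta definition is a stand-in convention; conclusions that depend
  on beta's absolute value (not its lignin trend) should fix the
  definition explicitly.
* Yield conventions for partially-consuming runs are reported in both
  variants rather than resolved.
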