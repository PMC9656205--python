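# Methods

This note documents the models, conventions and numerical choices behind
`synercomb`, and what the synthetic-data experiments do and do not show.

## Response scale and ingestion

All synergy computation runs on **% inhibition** (0 = untreated, 100 =
complete kill). Viability inputs are converted on ingestion
(inhibition = 100 − viability); raw plate signals are normalized against the
untreated control first. Inhibition is clipped to [0, 100] before
reference-model scoring — the Bliss product form needs fractions — but the
unclipped values are retained for Hill and MuSyC fitting, which should see
the raw data. Concentrations stay in nM throughout (a declared multiplier in
the reader dialect handles other units). Replicates are analyzed
independently and aggregated afterwards as mean ± sample SD (n − 1), except
where a joint fit is explicitly wanted (see the recovery experiment below).

## Monotherapy Hill fits

The four-parameter log-logistic model
`E(d) = E0 + (Emax − E0)·d^h / (C^h + d^h)` is fitted by unweighted least
squares with `C` and `h` on the log scale (positivity without constraints).
Initialization is deterministic: `C` starts at the measured dose whose
response is closest to the half-range, `h` starts from {0.5, 1, 2}, and the
best of the three starts by residual wins — identical inputs always give
identical fits. A flat response (zero total sum of squares) raises a
degenerate-fit error rather than returning an arbitrary curve. `r² = 1 −
SSres/SStot` is reported per fit; non-convergent fits carry `r² = −∞` and a
flag.

Two IC50-like quantities are reported and labelled, because they differ
whenever the curve plateaus below 100%: the **relative EC50** (parameter
`C`, the inflection midpoint) and the **absolute IC50** (the dose solving
`E(d) = 50`, undefined when `Emax < 50`). The **resistant fraction** is
`100 − Emax` on the inhibition scale — the cell population surviving
arbitrarily high dose.

ZIP-convention fits pin `E0 = 0, Emax = 100`, matching that model's
bounded-response assumption; conditional (curve-shift and ZIP) fits pin the
lower asymptote at the partner drug's fitted effect.

## Reference models and δ

Expected responses use **fitted monotherapy curves**, not raw edge wells:
ZIP requires fitted curves, and applying the same convention to Bliss, HSA
and Loewe keeps the four δ scores comparable (a raw-edge option exists via
`use_fitted_edges=False`). δ is averaged over **combination cells only**
(both doses > 0); monotherapy edges have zero expected interaction by
construction and would dilute the mean.

Loewe's dose-additivity equation is solved by bisection on the response to
an absolute tolerance of 1e-9, over the range from the larger `E0` to the
larger `Emax`; when the candidate response exceeds one drug's `Emax`, that
drug's equivalent dose is infinite and its term drops out, so the
expectation can climb to the more efficacious drug's plateau. A drug with
`Emax ≈ 0` therefore contributes nothing, as it should. The implementation
is cross-checked against a brute-force grid scan of the additivity equation
(step 1e-4) on 100 random parameter draws.

Two structural facts worth knowing when reading δ tables:

* `δ_HSA ≥ δ_Bliss` cell-wise always (the Bliss expectation dominates the
  HSA expectation for fractions in [0, 1]).
* ZIP is *not* exactly null under dose additivity. On a sham
  self-combination (a drug paired with itself) Loewe scores 0 to solver
  tolerance, but ZIP's 0/100-pinned conditional fits under-shoot a
  dose-additive surface with a resistant plateau; the observed bias on the
  default sham grid is about −3 percentage points. This is a property of
  the ZIP construction, not a bug.

Classification uses the conventional thresholds: δ ≥ 5 synergism, δ ≤ −5
antagonism (5 points being the typical noise level of large combination
screens), boundaries inclusive. Cross-model consensus: all models
synergistic → strong; some → weak; a synergism/antagonism mix → discordant.

## MuSyC surface

The two-drug response is the steady state of a four-state population — U
(unaffected), A1, A2 (affected by one drug), A12 (affected by both) — with
mass-action transitions whose rates are Hill-type in dose: U→A1 at
`d1^h1`, A1→U at `C1^h1`, A2→A12 at `(α21·d1)^(γ21·h1)`, A12→A2 at
`C1^(γ21·h1)`, and symmetrically for drug 2. The forward rate constants are
fixed at 1: only rate ratios matter at steady state, and fixing them removes
two unidentifiable parameters. The steady state is obtained by solving the
4×4 balance system with one row replaced by the normalization
`U + A1 + A2 + A12 = 1` (rows rescaled for conditioning; rate powers are
computed in log space and capped to avoid overflow during optimizer
exploration). The solution is verified against long-time integration of the
rate ODEs on random draws (occupancies agree to better than 1e-6).

With one dose zero the model reduces exactly to the single-drug Hill curve,
which is also the initialization route: asymptotes, slopes and EC50s start
from the monotherapy fits, `E3` from the minimum observed viability, and
the fold parameters from a small deterministic grid (α ∈ {1, 4, 0.25},
γ = 1), best start by residual.

Fitting runs on the **viability-fraction scale** (untreated ≈ 1) so that
β = `(min(E1,E2) − E3)/(E0 − min(E1,E2))` keeps its sign convention as a
fractional efficacy gain. Fold parameters are fitted in log space
(bounds 1e-5–1e5), Hill slopes within 0.05–20, and the asymptotes are
bounded near the observed response range with a floor just below zero
viability — a plateau far below anything measured is reachable only through
barely-populated states and is then unidentified; without the floor such
fits can send `E3` to physically meaningless values (more than 100% kill)
while improving the residual negligibly.

**Subscript convention.** `alpha21` scales the effective dose of *drug 1*
in cells already affected by drug 2 (the A2→A12 transition), and `gamma21`
scales drug 1's slope there; `alpha12`/`gamma12` are the mirror images.

**Instability flags.** Single-checkerboard fits can leave a fold parameter
essentially unconstrained (the hallmark is an enormous fitted value with a
larger dispersion). After each fit, every fold parameter is perturbed
100-fold; if the sum of squares changes by less than 0.1%, the parameter is
flagged unstable, reported unclipped, and excluded from aggregation means by
default.

## Gating and aggregation

Fits with `r² < 0.8` are excluded before aggregation, and kinetic-assay
analysis is restricted to the 28–80 h window: before the effect onset the
monotherapy curves are near-flat, no interaction model fits acceptably, and
the early fold parameters are wild. Aggregation is unweighted mean ± sample
SD at each level (over replicates, timepoints within the window, then
models or assays). The grand mean over per-model means equals the mean of
the pooled per-model values only when every model retains the same count —
the order-of-aggregation identity holds for complete tables and is tested.

## Non-compartmental PK

Destructive sampling yields one terminal sample per animal, so no real
per-animal profile exists. NCA metrics are computed on **index-paired
pseudo-profiles** (the k-th animal at each timepoint forms the k-th
profile); means match the profile-mean NCA exactly (the trapezoid is linear
in concentrations) and the SDs give a dispersion comparable across metrics.
This is a documented convention, not a claim about how any particular
reported SD was derived. AUC(0–t) uses the linear trapezoidal rule with a
prepended (0, 0) point for oral dosing (nothing is in circulation at dose
time); no extrapolation to infinity and no λz. Tmax is the earliest time
attaining the maximum. Concentrations below a configurable LLOQ are zeroed
before integration.

## Tumour growth inhibition

Volumes use the prolate ellipsoid `V = d²·D/2` with d the shorter calliper
axis (swapped with a warning if transcribed in the wrong order).
`TGI = 100·(1 − T/C)` is computed per treated animal against the
control-group *mean* (control uncertainty is not propagated into the SEM —
a documented choice), days matched within ±1 day for the 2–3×/week
schedule, and the reported maximum is the largest per-day group mean with
that day's SEM. Animals leaving the study contribute until their last
measurement.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *designs*: the 5×5 (12.5–200 nM × 0.25–4 nM,
72 h, 4 replicates) and 7×7 (62.5–4000 nM × 0.625–40 nM, 13 timepoints to
80 h, 3 replicates) checkerboards with zero-dose control edges; sparse oral
PK at 1.5/4/8/24 h with n = 3; and qdx3/qdx6 efficacy arms (control n = 11,
treated n = 6, start ~165 mm³, measurements 2–3×/week to day 14).

Defaults encode the observed study magnitudes: monotherapy EC50s of
65.7/0.58 nM (MTS-style) and 260.1/0.8 nM (RealTime-Glo-style); target Cmax
values per analyte/tissue with absorption rates chosen to reproduce the
observed Tmax (ka = 2/h for the MDM2 inhibitor → Tmax 1.5 h; ka = 0.35/h
for the MEK inhibitor → Tmax 4 h — note that ka = 1/h would peak at the 4 h
sample instead); combination exposure multipliers matching the observed
interaction directions (MDM2-inhibitor exposure up ×1.14–1.22, MEK-inhibitor
plasma exposure down ×0.80); and daily kill factors back-computed from the
per-arm maximum TGI via `TGI = 1 − (1 − kill)^n_doses` (0.387/0.319/0.415
for the single-agent and combination arms). Plate noise is additive Gaussian
on % response (default SD 3); biological PK/tumour variability is
log-normal. Time-dependence of the in vitro effect is a linear onset ramp:
no effect before 24 h, full effect at 80 h.

What passing tests on these data *show*: the estimators are calibrated
(nulls score ≈ 0), consistent (noise → 0 recovers truth), and correctly
ranked (stronger truth → stronger score). What they *cannot* show: behaviour
under real plate artefacts (edge effects, drift, heteroscedastic noise),
real PK absorption kinetics, or real tumour growth heterogeneity — the
generator's noise model is deliberately the simplest one consistent with
the designs.

## The β-recovery experiment

Recovering MuSyC's efficacy synergy β from a *single* noisy checkerboard is
information-limited: at 5-point noise on the 7×7-plus-controls grid, the
Cramér–Rao bound for the 12-parameter fit puts the median absolute error of
β̂ near 0.075 regardless of estimator. The recovery experiment therefore
uses the replicated design (n = 3, as in the kinetic assay) and fits the
replicate-mean matrix — for i.i.d. Gaussian noise this is exactly the joint
maximum-likelihood fit over all wells. At that design the bound's median is
≈ 0.043 and the measured median over 20-seed blocks is 0.04–0.06; the
statistic genuinely sits at its information limit, so seed-to-seed
variation around 0.05 is expected and honest, not a convergence defect.

## Known limitations

* No bootstrap confidence intervals for fitted parameters (no raw wells to
  resample); the instability flag is a cruder but honest substitute.
* ZIP's conditional fits fall back to the plain Bliss expectation (flagged)
  when a row or column cannot be fitted; heavily degenerate matrices can
  therefore carry partly unconditioned ZIP scores.
* The Loewe solver assumes both curves are increasing on the inhibition
  scale; paradoxical (non-monotone) dose-response is out of scope.
* Three-or-more-drug surfaces, PBPK/PD modelling and mechanistic biology
  are out of scope throughout.
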