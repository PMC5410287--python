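# Methods

This note documents the models, the numerical choices, the shipped default
parameters and what the synthetic-data generators do and do not emulate.

## Pharmacokinetics

Each drug follows a one-compartment model with first-order absorption from
the intraperitoneal depot. A dose `D` given at time `t0` contributes the
Bateman profile

    c(t) = D · scale · ka/(ka−ke) · (exp(−ke·(t−t0)) − exp(−ka·(t−t0)))

for `t ≥ t0`, zero before; multi-dose schedules superpose linearly. The
intraperitoneal route is treated as equivalent to intravenous dosing with
first-order absorption — no route-specific bioavailability parameter.

**Identifiability of the amplitude.** The PD potencies `e_txl`, `e_beva`
multiply the concentration wherever it appears, so the absolute volume of
distribution cannot be identified jointly with them. `scale` therefore
defaults to `ke`, which makes a unit dose have unit area under the curve;
the potencies absorb any residual constant. Anyone with measured PK can
override `scale` per drug.

**Defaults** (`data/pk_params.synthetic.yaml`, all rates 1/day):

| drug | ka | ke | rationale |
| --- | --- | --- | --- |
| paclitaxel | 40 | ln2/0.125 ≈ 5.55 | 3-hour terminal half-life, fast IP absorption |
| bevacizumab | ln2/0.5 ≈ 1.39 | ln2/1 ≈ 0.69 | *effective* 1-day half-life, see below |

The bevacizumab value is deliberately the half-life of the *normalization
stimulus*, not of the circulating antibody (which persists for many days in
mouse serum). The dynamic model reads `A(t)` as the drive that prunes
immature vessels; experimentally the normalization window lasts days, not
weeks, and an effective 1-day decay places the window on that scale. This
is a modelling choice made once when the defaults were frozen; with
measured PK and potencies fitted to data, the window emerges from the fit
instead.

## Pharmacodynamics

State units are fold-increases of the initial bioluminescence signal;
`V(t_I) = 1` at the first observation day `t_I = 8`. Killed cells traverse
three transit compartments (`k = 1/day` by default) before removal, so the
observed burden `N = V + Z1 + Z2 + Z3` responds to the cytotoxic with a
realistic delay. The tumor kill term `e_txl · (capacity) · Q · C · V`
scales with both the vasculature available for delivery and its quality.

**Vascular kill variants.** Endothelial cells are taken to be ~5× more
sensitive to paclitaxel than tumor cells. Two readings of the vascular
kill term are implemented:

* `combined` (API default): `(e_beva·A + 5·e_txl·C) · delivery · pool` —
  both drugs prune the vasculature, each through its own concentration.
* `literal`: `(e_beva + 5·e_ct) · delivery · A · pool` — the pruning is
  driven by the antiangiogenic concentration alone (`e_ct` defaults to
  `e_txl`).

`delivery` is `K·Q` (model 1) or `S·Q` (model 2), the same modulation the
tumor kill term uses; `pool` is the targeted compartment (`K` or `U`).

**Why the representative model-2 set pairs with `literal`.** Under the
combined reading every paclitaxel dose wipes the unstable pool within
hours (the concentration spike times the 5× sensitivity), instantly
re-normalizing the vasculature. Each later dose then meets a high-quality
vasculature regardless of the gap, and because Gompertz dynamics forget
early perturbations at rate `a` (a kill at time `t` affects the day-52
burden in proportion to `exp(−a·(52−t))`), delaying paclitaxel is then
*always* beneficial: the scan has no interior optimum. Under the literal
reading the window opens and closes through bevacizumab decay and
unstable-vessel regrowth, paclitaxel feeds back only through the tumor
(`V` drops → the `bV` stimulation of `U` drops → `Q` rises — the second
normalization phase), and an interior optimum with a detrimental long gap
emerges. The literal term is therefore what the representative defaults
and the window-structure tests use; `combined` remains the API default for
users who want both pharmacological effects active.

**Initial vascular state (model 2).** `U0 = 0` and `S0 = K0`, so quality
starts at its baseline of 1 and degrades as the growing tumor floods the
unstable pool — matching the observed initial drop. Both are overridable.

**Quality policy (model 1).** Arms the two-arm comparison does not define
(Control, monotherapies, reversed sequence) default to `Q = 1`; the drug
terms vanish where the drug is absent, so the choice only matters for
monotherapy arms and is exposed via `GroupSpec.quality`.

**τ (stable-vessel loss).** Calibration consistently drives it below
numerical noise, so it is pinned at 0 by default but kept in the model for
systems where stable vessels do regress.

## Numerics

* Stiff integration with `scipy.integrate.solve_ivp` (LSODA),
  `rtol = 1e-9`, `atol = 1e-12` by default; fitting loops may relax `rtol`
  to ~1e-6 for speed.
* Integration restarts at every dose time so the kink in the forcing
  derivative never straddles a solver step.
* States are integrated in their natural form, no clamping; a state
  leaving its domain (V ≤ 0, S+U ≤ 0, non-finite) raises a diagnostic
  error naming the arm and time.
* Nelder–Mead runs in log-parameter space (positivity for free;
  scale-free simplex steps). Failed simulations inside the optimizer
  return a finite penalty (1e12 + distance from bounds), never an
  exception.
* Multi-start, when enabled, is a deterministic log-spaced grid
  (3 points per parameter, factors ¼/1/4, capped at 81 starts) — an
  automated stand-in for manual exploration of parameter space.
* Standard errors: `σ² = J_min/(n−p)`, covariance `σ²(SᵀS)⁻¹` with `S`
  the central-finite-difference sensitivity of predictions (relative step
  1e-4, balancing truncation against solver noise). A singular `SᵀS` is
  reported with the names of the flat parameter directions. The fit is
  unweighted by default — matching the reference estimation procedure
  despite heteroscedastic bioluminescence — with an optional `1/sem²`
  weighting flag.
* Gap-scan argmin ties break toward the smaller gap (earlier
  chemotherapy, the clinically conservative choice). "Tumor size" for the
  reduction metric is the total burden `N` (what bioluminescence
  measures); `V` alone is selectable.

## Shipped default parameters

`data/model_params.synthetic.yaml` is a *synthetic, representative* set,
not a fit to any animal data (the originating study's fitted values were
published only as supplementary material that is not redistributed here).
The defaults were chosen once, against the printed in-vivo anchors of the
system — an untreated arm near 190-fold burden at day 52, a concomitant
arm at ~0.55× control, a 3-day sequential arm at ~0.27× control, a
concomitant-arm quality of ~0.2 — and then frozen. The two models carry
separate growth parameters because they are alternative descriptions
calibrated independently; in model 2 the stable pool is large and nearly
frozen (`K0 = 150`, `χ = 0.003`) so the delivery factor `S·Q` tracks the
quality window rather than tumor-driven vasculature growth.

With these defaults the dynamic model places the optimal
bevacizumab→paclitaxel gap at ~3 days with a ~48% day-52 burden reduction
versus concomitant dosing, and makes an 8-day gap slightly worse than
concomitant dosing. These numbers characterize the shipped synthetic
world; they are not measurements.

## Synthetic data

The growth generator simulates each arm at the true parameters and
multiplies per-animal trajectories by i.i.d. lognormal noise with mean 1
(bioluminescence error is multiplicative; default CV 0.3 mirrors the large
scatter typical of such studies, e.g. group means reported ±60% s.e.m.).
Means and s.e.m. over the simulated animals (8/arm for the six-arm
template, 12/arm for the three-arm template) are returned in the exact
shape the calibration consumes.

Metastasis onsets come from an inhomogeneous exponential clock with hazard
`λ(t) = β·N(t)` (time-rescaling of unit-exponential draws), censored at
study end. This hazard model is an invented, documented stand-in — the
growth models make no claim about metastasis — and exists to exercise the
incidence statistics; because the clock starts at the first observation
day, the metastatic index saturates at `(T − t_I)/T`, not 1.

What a green test therefore establishes: the pipeline recovers parameters
it generated, its oracles (closed forms, fixed-step integration, grid
search, OLS formulas) agree with the implementations, and the shipped
world reproduces the qualitative biology (normalization window, two-phase
quality dynamics, ordering of arms). What it does not establish: agreement
with any real animal's kinetics, inter-animal correlation structure,
site-specific metastasis biology, or PK beyond the two-exponential shape.

## Known limitations

* Group-mean fitting only; no mixed-effects treatment of per-animal
  curves, no bootstrap or profile-likelihood intervals (asymptotic SEs
  only, with an optional bootstrap hook left to the caller).
* Censoring in the metastasis statistics is non-informative; death
  without metastasis is treated as censoring at death (no competing-risks
  correction).
* The gap scan varies only the intra-cycle gap — doses, cycle count and
  inter-cycle interval are fixed by the design.
* No spatial vasculature, interstitial pressure, or ligand-binding
  mechanisms; the models are deliberately phenomenological.
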