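# Methods

## The screening design

`eescreen` uses radial one-at-a-time elementary effects rather than
linked Morris trajectories: every repeat draws a fresh base point, so
repeats are independent and the campaign shards trivially by parameter.
Parameters are unit-normalised with their physiological `[low, high]`
range; the region of experimentation is the regular `p`-level grid on
the unit hypercube (`p = 11` by default), and the perturbation is
`delta = 0.1` of the unit range — one grid step. Neither value is
forced by the method; both are configurable per campaign. Before a
perturbation in direction `+` (`-`), the base coordinate is required to
satisfy `x_i <= 1 - delta` (`x_i >= delta`); an inadmissible coordinate
is *resampled uniformly over the admissible grid levels* rather than
reflected, which preserves uniformity over the admissible region at the
cost of a slightly non-uniform marginal at the boundaries. Perturbed
points therefore always remain on the grid and inside the hypercube.

The elementary effect is normalised by the pre-perturbation output
value, not by the perturbation size: `d_i = s (v(t) - v_base)/|v_base|`
with `s = +1` for increments, `-1` for decrements. The sign flip makes
increment and decrement samples estimates of the same derivative-like
quantity, so they can be pooled; per-direction means are retained in
the aggregated table (`mean_pos`, `mean_neg`) because the equality of
the two is itself informative (it fails in curved regions of the
response). A division guard `|v_base| <= 1e-12` flags the sample as
missing rather than zeroing it; missing samples are excluded from
aggregation and their counts reported.

## The two-phase steady-state protocol

Each phase simulates four weeks (40,320 min). Phase one settles the
model from its default initial state at the base point; phase two
continues from that state with one coordinate shifted and records all
outputs at offsets {1 min, 1 h, 24 h, 1 week, 4 weeks} after the
perturbation — the ladder on which short-lived (hormone-like) and
permanent (renal) effects separate.

Two acceptance rules apply to every phase:

* **Survival ("aliveness")**: GFR >= 0.015 L/min, serum sodium in
  [120, 160] mEq/L, serum potassium in [2.5, 8] mEq/L, hematocrit in
  [24, 80], MAP in [50, 200] mmHg, heart rate in [20, 200] /min,
  inclusive at the boundaries. Bounds are enforced *continuously*:
  adapters may register them as terminal root-finding events (the
  bundled model does), and the engine independently re-checks every
  recorded snapshot. Variables a model does not expose are skipped and
  logged once.
* **Pseudo-steady state**: the relative change of every recorded output
  over the final simulated day must stay below `steady_tol = 1e-4`.
  The model never reaches the exact fixed point in finite time, so all
  "steady" outputs carry a residual of order `steady_tol` per day times
  the slow time constant — about 1e-4 relative for the bundled model's
  sodium state. Tests and oracle comparisons account for this floor.

A failed phase discards the attempt and resamples the base point, up to
`max_restarts` per repeat (then a hard error — a campaign never
silently under-fills). Discard counts are reported by reason and phase
in the campaign manifest. Under the bundled model's defaults the
acceptance rate is roughly 10% (the survival bounds are doing real
work), so campaign-scale runs set `max_restarts` well above the ~10
restarts needed on average; the package default of 100 keeps one-off
runs from spinning.

Reproducibility: the master seed spawns one child stream per
(parameter, direction, repeat) slot via `numpy.random.SeedSequence`, so
results are bitwise-reproducible and independent of execution order,
including under restarts.

## The bundled demonstration model (`demo-pn`)

A three-state reduction of long-term pressure regulation:

    dVB/dt  = W_in - UO                      blood volume (L)
    dTPR/dt = (TPR0 (CO/CO_ref)^g - TPR)/tau peripheral resistance
    dNA/dt  = NID_d - CNA * UO               sodium mass (mEq)

    CO = max(0, c (VB - VB0));  MAP = CO * TPR
    UO = UO_b + k_r max(0, MAP - P_set);  CNA = NA / VB

The pressure-natriuresis curve `UO(MAP)` forces `UO = W_in` at steady
state, hence the closed form

    MAP* = P_set + (W_in - UO_b)/k_r
    CO*  = (MAP* CO_ref^g / TPR0)^(1/(1+g));  TPR* = MAP*/CO*
    VB*  = VB0 + CO*/c;  CNA* = NID_d/W_in;  VUD* = W_in

Defaults (`k_r = 2.5e-4 L/min/mmHg`, `P_set = 96 mmHg`,
`W_in = 1e-3 L/min`, `c = 4 /min`, `VB0 = 3.75 L`, `TPR0 = 20
mmHg·min/L`, `CO_ref = 5 L/min`, `g = 1`, `tau = 400 min`,
`NID_d = 0.14 mEq/min`, `UO_b = 0`) give the round steady state
MAP\* = 100, CO\* = 5, TPR\* = 20, VB\* = 5, CNA\* = 140. The campaign
table spans `[0.5, 1.5]×default` for nine parameters; `UO_b` (default
0) and `g` (default 1) stay fixed because a multiplicative range around
them is degenerate or redundant.

Design notes, all deliberate:

* The default initial state (VB = 5.2 L, TPR = 19, NA = 700 mEq) is
  off-steady so the settling phase is exercised; NA = 700 puts initial
  serum sodium at 134.6 mEq/L, inside the survival band.
* Timescale separation is the point of the fixture. The renal servo
  restores MAP with time constant `1/(k_r c TPR)` ≈ 50 min; blood-flow
  autoregulation drifts with `tau = 400` min; sodium equilibrates with
  `VB/W_in` ≈ 5000 min (3.5 days). A step in `TPR0` therefore leaks
  into MAP at the one-hour record time (peak normalised effect ≈ 0.01)
  and is fully compensated at four weeks (< 1e-6) — the
  transient-but-not-permanent signature of infinite renal gain. `tau`
  much larger would flatten the peak below detectability (the leak
  scales as the ratio of the two time constants); much smaller would
  move it inside the first record time.
* The sampled ranges straddle the hypertension threshold: MAP\* spans
  roughly 49–156 mmHg, so stratification at 106.67 mmHg yields both
  phenotypes in every campaign, and the MAP ceiling/floor plus the
  serum-sodium band (`CNA* = NID_d/W_in` in [120, 160]) produce
  realistic discard traffic.
* `NID_d` influences serum sodium only — it is the designed null
  control for effects on pressure. Note one non-obvious consequence of
  survival truncation: *in accepted individuals* `NID_d` is strongly
  coupled to `W_in` (their ratio is confined to the sodium band), so
  rank screens involving `W_in` see a shadow of it in `NID_d`. This is
  a property of survivor populations, not an artifact.

What the fixture does **not** emulate: hormones, heart rate,
hematocrit, oncotic pressures, or any short-timescale cardiovascular
dynamics; its parameter count (9) is far below a whole-body model's
(~100). Passing the oracle tests shows the *machinery* — sampling,
settling, survival monitoring, effect normalisation, aggregation,
stratification, screening, classification — is correct, not that any
physiological conclusion transfers to a particular full-scale model.

## Populations, densities, screens, classifiers

Every accepted simulation contributes a pre- and a post-perturbation
individual; both phases are pooled by default in stratification,
correlation and classification (switchable), since steady phenotype
proportions barely differ between phases. The hypertension threshold is
always *derived* from the cuff definition via MAP = DBP + (SBP−DBP)/3
(140/90 → 106.67 mmHg; 160/95 → 116.67 mmHg), inclusive on the
hypertensive side, unless explicitly overridden.

MAP densities are fitted by maximum likelihood in the gamma family with
location fixed at zero; the chi-squared fit is the same family with the
scale pinned at 2 (equivalently, degrees of freedom = 2·shape), so the
free-gamma log-likelihood bounds the chi-squared one from above by
construction.

All correlation screens are Spearman (average ranks for ties), because
the relationships of interest are monotone but not linear; constant
inputs yield a missing value rather than a number. The interaction
screen correlates the *signed* elementary-effect samples of one
(parameter, output) pair against each co-sampled parameter's base
value; a large |rho| nominates that parameter for joint multi-parameter
perturbation. Strata comparisons categorise each (parameter, variable)
pair as increased / decreased / sign-flip / unchanged on absolute
magnitudes, with a display threshold (default |rho| >= 0.1) below
which pairs are called unchanged. No multiple-testing correction is
applied; sample counts are always emitted so users can apply their own.

Classifiers are binomial GLMs fitted by IRLS on physical-scale
parameters. Stepwise reduction is backward-only under AIC (drop the
predictor whose removal lowers AIC most; stop at a local minimum), so
the reduced model's AIC never exceeds the full model's. Evaluation
splits the population at a configurable train fraction (default 0.5,
resampling the split if a class is missing on either side), scores the
held-out half, and computes AUC by the tie-corrected rank estimator;
the ROC curve groups tied scores into single vertices so its trapezoid
area equals the rank AUC exactly. Perfect separation — common when
predictors determine the phenotype deterministically, as with the demo
model's `{k_r, P_set, W_in}` — is reported via a warning and a
`converged = False` flag rather than an error, because separable fits
still rank held-out individuals correctly. Classifier sensitivity
sweeps each predictor over its physical range with the others at
defaults and reports the range of predicted probability.

## Numerical choices

* Integrator: LSODA (stiff-capable) with `rtol = 1e-8` (configurable),
  absolute tolerances scaled per state. Oracle agreements in the test
  suite are stable to a 10× tightening.
* Steady tolerance `1e-4`/day; division guard `1e-12`; grid tie-breaks
  never arise (levels are exact multiples of `1/(p-1)` compared with a
  `1e-9` tolerance).
* Degenerate inputs: empty populations stratify to two empty subsets;
  constant samples refuse a density fit; single-class labels refuse a
  classifier; sub-minimum sample counts make screens return missing.

## Problem sizes

The shipped tests and the acceptance script use the desk-scale campaign
the analytic oracle supports: nine parameters × two directions × 50
accepted repeats = 900 accepted simulations (≈ 10,000 attempted
four-week integrations, about a minute on one CPU). The engine's
defaults (`repeats_per_direction = 1000`) correspond to a full-scale
campaign of a ~100-parameter model (2·k·r simulations, 4·k·r virtual
individuals); nothing in the code path differs at that scale beyond
wall-clock time.

## Known limitations

* Parameters are sampled independently and uniformly on the grid; no
  correlated priors.
* One parameter per perturbation; the interaction screen only
  *nominates* combinations for future multi-parameter designs.
* No Morris trajectory designs (independent radial samples only).
* Linear GLM classifiers only; no regularisation or nonlinear terms.
* The deposited-population loader needs a user-supplied column mapping;
  it makes no attempt to guess schemas.
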