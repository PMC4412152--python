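# Methods

## Well normalization and plate standardization

The measurement model assumed throughout is multiplicative nuisance on
counts: `Luc = gain_plate · eff_well · response` and
`RL = eff_well · rl_mean`, where `eff_well` is the well's transfection
efficiency/viability and `gain_plate` collects plate-level factors
(reader gain, incubation, cell density). The ratio `Luc/RL` cancels
`eff_well`; dividing a plate's ratios by its standard-well scale factor
`s = mean(agonist standards) − mean(diluent standards)` cancels
`gain_plate`. After both steps the on-plate standard difference is 1 by
construction, which is the identity the test suite and the acceptance
script verify to machine precision. A plate whose standard fails to
respond (`s ≤ 0`) is flagged and excluded rather than raising, since a
dead standard invalidates only that plate; a failed *baseline* plate
aborts the run, because nothing else in the run can then be scored.

Each plate — the baseline plate included — is standardized by its own
standard wells, not by another plate's. Within a run, replicated
receptor/odor measurements are averaged before ranking; separate runs
(dates) are scored independently and pooled.

## Hit selection

The selection budget is `floor(0.05 · N)` pairs, with at most ten ligands
per receptor. The cap acts as a restriction inside the budget: pairs a
cap removes are not backfilled by lower-ranked pairs, so the selected
count can fall below the budget. Floor rounding is the conservative
choice; ties are broken by (delta descending, receptor id, odor id) so
selection is reproducible. Both the fraction and cap are parameters.

## Secondary ANOVA filter

A one-way fixed-effects ANOVA across the concentration groups, with the
no-odor control entering as a factor level rather than being subtracted.
alpha = 0.05 per pair with no multiple-testing correction, matching how
such screens are conventionally filtered; a Benjamini–Hochberg option
exists but is off by default. Degenerate inputs have defined outcomes
instead of errors: all observations identical → (F, p) = (0, 1); zero
within-group variance with real between-group spread → (F, p) = (∞, 0),
flagged. Null calibration (rejection rate 0.05 under i.i.d. groups) is
checked by simulation in the test suite.

## Dose-response model and fitting

The curve is the three-parameter log-logistic in log10 molar units,
`y = bottom + (top − bottom)/(1 + 10^(hill·(logEC50 − x)))`, Hill slope
fixed at 1 by default (the classic "sigmoidal dose-response" of the
standard fitting tools); `fix_hill=None` frees the slope. No-odor wells
enter at x = −12 as a far-left anchor.

Fitting is `scipy.optimize.least_squares` (trust-region reflective) with
an analytic Jacobian and deterministic multi-start: bottom/top start at
the mean responses at the lowest and highest tested concentrations, and
log EC50 starts at every midpoint of consecutive observed concentrations;
the lowest-RSS solution wins, so fits are reproducible. Box constraints
keep the solution inside the tested region — bottom and top within the
observed response range widened by one spread, log EC50 within the tested
concentration range ± 2 log units. This matters for flat or one-sided
series, where the unconstrained problem is unidentifiable and the span
`top − bottom` can otherwise diverge along a ridge, manufacturing
spurious CI separation; bounded, such series converge to a tame
near-degenerate fit whose wide intervals correctly fail the agonist
criteria. A consequence is that the fit never claims an EC50 far beyond
the tested range, which is the scientifically defensible behavior.

Standard errors come from the asymptotic covariance `RSS/df · (JᵀJ)⁻¹`
(pseudo-inverse when near-singular) and 95% CIs are `estimate ±
t(0.975, df) · se`; profile-likelihood intervals are out of scope. The
"standard deviation of the fitted log EC50" in the second agonist
criterion is this standard error, and the criterion is strict
(`se < 1`, so exactly 1.0 fails). Fits require positive residual degrees
of freedom; non-convergence sets `converged=False` and vetoes the call
with a reason code, never raises.

## Extra sum-of-squares test

The nested comparison fits (null) one shared sigmoid to the pooled
receptor + empty-vector points versus (alternative) separate sigmoids,
`F = ((RSS₀ − RSS₁)/(p₁ − p₀)) / (RSS₁/df₁)`. The shared-sigmoid null is
the most literal "same curve for both conditions" nesting; a flat-null
variant (single constant) is available for sensitivity analysis.
Rejection is one-sided: besides p < alpha, the receptor fit's span must
exceed the vector fit's span, so a responsive control can never count as
receptor activation. Reported EC50s are rounded to the nearest integer
log unit with exact halves going to the more negative (more potent) side;
repeated experiments on the same pair stay as separate table rows.

## ROC validation

Stage-k scores (primary delta, secondary F) are scored against stage-k+1
outcomes (secondary pass, agonist call). Curves are tie-grouped — one
vertex per distinct score — and AUC is the trapezoidal area, identical to
the Mann–Whitney U statistic normalized by `n_pos · n_neg` with half
credit for ties; the tests verify this equivalence against exhaustive
pair counting. Infinite F statistics (degenerate ANOVA) rank above all
finite scores. By default the standardized baseline-subtracted delta is
the primary-screen predictor; raw scores can be supplied instead.

## Synthetic screen generator

The generator emits the deposited tab-separated schemas exactly
(sentinels 9999/0/−12, MM/DD/YY dates, integer-style IDs) so the same
parsers and pipeline run on synthetic and real tables. Structure per run:
twelve 96-well plates sharing one receptor-to-well assignment — one
all-diluent baseline plate plus eleven odor plates — with 85 test wells,
five broadly tuned receptors, and 3+3 Olfr544 standard wells per plate.
Wells left over when a receptor block is short are padded with the
empty-vector control.

Generative model per well: response = receptor baseline + efficacy ·
occupancy + N(0, σ), with occupancy `c/(c + EC50)` (Hill 1, matching the
fitted model so recovery tests are well-posed); counts are
`Luc = gain · eff · response` and `RL = eff · rl_mean · (1 + noise)` with
lognormal plate gain (σ_log 0.2) and well efficiency (σ_log 0.15) —
exactly the nuisance structure the normalization removes. Defaults mirror
the study design: 511 receptors × 73 odorants, primary challenge at
100 µM, secondary ladder {0, 1, 10, 100} µM in triplicate, dose ladder
10 nM–10 mM in half-log steps plus the −12 anchor in triplicate. Latent
agonist pairs are sparse (density 0.005 by default, the order observed in
such screens), with log EC50 uniform on [−8, −4] and efficacy uniform on
[0.8, 1.5] response units; response noise σ = 0.05 response units.
Receptor baselines are lognormal around 0.2 so constitutive activity
varies across clones.

What the simulator does *not* emulate: plate spatial (edge/row) effects,
receptor-specific expression failures, odorant carryover or volatility
cross-talk, non-competitive or biphasic responses, and day-to-day drift
beyond plate gain. Passing tests therefore demonstrate the pipeline's
correctness and calibration under the assumed measurement model, not
robustness to those real-data pathologies.

## Problem sizes used in tests

Unit and acceptance tests run on one-run screens (85 receptors × 11
odors; 1,152 wells), 2,000 simulated null pairs for ANOVA calibration,
200 planted agonists and 500 nulls for dose-response operating
characteristics, and brute-force oracles at n ≤ 100 — sizes chosen so the
statistical assertions have tight binomial tolerances while the whole
suite stays fast on a single core. The full-scale default configuration
(511 × 73) runs through the same code paths.

## Known limitations

- CIs are asymptotic; coverage can be optimistic for short or one-sided
  dose series (partly mitigated by the −12 anchor and the bounded fit).
- The extra-SS span gate compares fitted spans, which for two flat series
  of different constitutive level is a near-tie decided by noise; the
  composite call is still protected by the CI-separation criterion.
- The ANOVA treats triplicates as independent, as the assay's design
  intends (separate wells from one parent cell plate); true plate-level
  correlation would inflate the effective alpha.
- The selection rule is the documented 5%/cap-10 policy; pairs admitted
  to the real secondary screen ad hoc before the primary screen finished
  are outside its scope.
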