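# Methods

This note documents the models and procedures implemented in `efmt`, the
defaults chosen where the underlying study protocol leaves details open, and
what the simulation studies do and do not establish.

## The training task

The task is a continuous-performance N-back over category labels. Stimuli are
metadata only: an emotion label drawn from {happy, sad, angry, fearful,
surprised, neutral} on a face identity (active task), or a shape label from
{circle, square, triangle, star, diamond, hexagon} (control task). Each item
is presented for 1 s followed by a 1 s fixation cross; for every scored item
the participant judges whether the current label matches the label N items
earlier. A session is 15 blocks. Session 1 starts at N = 1; later sessions
start where the previous session's staircase ended.

Block construction. A block presents `n_scored_items + N` items; the first N
are unscored context. Exactly `round(target_rate * n_scored_items)` scored
items are targets (label repeats at lag N) and
`round(lure_rate * n_scored_items)` are lures (label repeats at lag N±1 but
not at lag N; for N = 1 only lag N+1 is defined, since lag 0 would be the
item itself). All remaining scored items carry labels that differ from the
labels at lags N and N±1, which requires at least three categories; a
single-category set is accepted only as the degenerate all-target design.
Construction is by bounded resampling: label placements that leave a lure no
feasible label (both lag-N±1 labels equal to the lag-N label) trigger a
re-draw of the block, with a hard failure after 1000 attempts.

Defaults where the protocol is silent (all configurable):

| parameter | default | rationale |
|---|---|---|
| scored items per block | 15 | keeps a 15-block session in the 20–35 min envelope at 2 s/item |
| target rate | 1/3 | standard N-back construction |
| lure rate | 0.2 | forces lag-specific memory |
| staircase up / down threshold | 0.85 / 0.60 | common adaptive N-back practice |
| N bounds | [1, 15] | N cannot exceed the scored-item count |
| carryover rule | "last" | next session starts at the post-update level of the final block |

Omitted responses score as errors; they are tabulated with the error cell of
their item type (miss on targets, false alarm otherwise) so the four counts
always sum to the scored-item count. `end_n` is the level a 16th block would
have used, i.e. the staircase update applied to block 15 — this is what the
"last" carryover rule hands to the next session.

Simulated observers. A responder's correct-judgment probability is
`0.5 + (0.5 − lapse) · logistic(−(N − κ)/s)`, clipped to [0.05, 1]: κ
("capacity") is the load at 75% accuracy midway between chance and ceiling,
`s` the slope, and `bias_negative` an additional error rate applied to face
stimuli only. Accuracy is non-increasing in N by construction. Under the
default thresholds the staircase equilibrates with long-run mean block level
within about one unit of κ, which the test suite checks empirically.

## The simulated cohort

The cohort generator reproduces the statistical structure the trial analysis
assumes, not depression pathophysiology.

Baselines. Eligible severity is 17-item Ham-D in [16, 27]. Baselines are
rounded draws from a truncated normal confined to that window whose latent
location is solved (Brent's method on the truncated-normal mean) so the
*truncated* mean equals the configured arm mean — naive truncation at the
default window would inflate the mean by about +0.5 points. Working-memory
composites (mean scaled score of Digit-Span Forward/Backward and
Letter-Number Sequencing) are Normal(10.9, 0.8); the composite function is
the plain arithmetic mean of the three scaled scores.

Weekly means. The control arm declines linearly from 19.48 to 14.71 over
weeks 0..6. The control-minus-active difference is anchored at 0.2283
(baseline), 3.1462 (week 3) and 3.8681 (week 6) and linearly interpolated
between anchors; the active curve is the control curve minus that
difference. This makes both arm curves monotone decreasing, pins the
baseline/week-3/week-6 contrasts exactly, and puts the active week-6 mean at
10.84. (Using all seven reported weekly differences verbatim would produce a
non-monotone active-arm mean curve; the anchored interpolation was chosen
instead.)

Residuals. Within-participant errors over the seven visits are multivariate
normal with a compound-symmetry covariance, SD 4.9 Ham-D points and
correlation 0.5 — consistent with the reported contrast standard errors and
the protocol's power-analysis correlation — stored as a full dense matrix so
the unstructured-covariance machinery downstream is genuinely exercised.
Totals are rounded and clipped to the instrument range [0, 52]; week 0 is
replaced by the sampled eligible baseline.

Adherence and dose. Each of the 18 scheduled sessions (3/week, 6 weeks) is
attended independently with probability 0.88, chosen to reproduce roughly
73% regimen completion under the protocol's two discontinuation rules (fewer
than two sessions in any week; more than three missed cumulatively). A
participant discontinued in week w misses the week-w assessment onward, so
week-1 discontinuation means no post-baseline rating and exclusion from the
modified intention-to-treat (m-ITT) sample. The active arm receives a dose
term `dose_effect · (cumulative sessions − expected cumulative sessions)`;
centering on the expectation keeps the configured weekly means the realized
means. The default `dose_effect = −0.7` per session follows from requiring a
sessions-versus-percent-change correlation near −0.5: with sessions-total SD
σ_s ≈ 4–5 (driven by dropouts) and change-score SD σ_c = 4.9 under compound
symmetry, r ≈ d·σ_s / sqrt(σ_c² + d²σ_s²) gives d ≈ 0.5–0.7.

Item scores. Totals are split across the 17 Ham-D items (nine 0–4 items,
eight 0–2 items; maximum 52) by a multinomial draw proportional to a weight
profile (default: proportional to item maxima), with stochastic
redistribution of points exceeding an item's cap. The split conserves the
total exactly and respects every item range. BDI-II is a per-arm linear
transform of the Ham-D total (computed from the configured endpoint anchors)
plus Normal(0, 3) noise, clipped to [0, 63].

## Randomization and trial orchestration

Allocation uses permuted blocks of six at a 1:1 target: each complete block
contains exactly three assignments per arm in random order, and a final
partial block is the leading part of one more permuted balanced block, so
total imbalance never exceeds three. The protocol's additional
completer-proportion balancing is not algorithmically specified anywhere and
is deliberately not guessed; plain permuted blocks are used.

`run_trial` enrolls, randomizes, draws each participant's profile and
adherence, optionally runs every attended session through the task engine
(capacities Normal(3.4, 1.7) active / Normal(4.4, 2.0) control, clipped to
[1, 12]), simulates the weekly ratings, and assembles long-format,
participant-level and allocation tables. ITT is everyone randomized; m-ITT
requires at least one week of training and one post-baseline rating.
Everything is driven by one seeded generator: identical configuration and
seed reproduce the output CSVs byte-identically.

LOCF. The sensitivity dataset carries the last observed Ham-D total, item
scores and BDI forward to every missed week for m-ITT participants, flags
carried rows, and is idempotent. Clinical response is at least 50% Ham-D
reduction from baseline (boundary inclusive), evaluated on the week-6
(LOCF-completed) value; participants with no usable outcome get an explicit
missing flag and count as non-responders in summaries.

## Statistical analysis

MMRM. The primary model is a fixed-effects cell-means model (arm × visit,
visit categorical) with one unstructured 7×7 within-participant covariance,
fitted by REML (default; ML available). Fixed effects are profiled out by
generalized least squares and the restricted likelihood is maximized over
the Cholesky factor of the covariance (log-parametrized diagonal) with
L-BFGS-B; subjects are grouped by missingness pattern for speed. On complete
data the estimates have a closed form — cell means and the pooled within-arm
residual covariance with divisor N − (number of arms) — which the fitter
uses directly. Missing visits contribute through the marginal likelihood of
the observed subset; no imputation. If the optimizer fails from the
moment-based start it is restarted from compound-symmetry start values and
the convergence flag is reported. Correctness is checked against two
independent oracles: direct GLS matrix algebra on complete balanced data,
and a from-scratch Nelder-Mead maximization of the same restricted
likelihood on a small incomplete dataset.

LS means are the model cell means; weekly contrasts are control minus
active, so positive values favour the active arm on a severity scale. The
per-week contrast t uses the residual-degrees-of-freedom convention (total
observations minus fixed-effect parameters), the convention that matches the
published table's df; the method name is recorded in the output. For the
omnibus group × visit test the Wald statistic of the six
difference-in-differences contrasts is converted to F with the multivariate
(Hotelling T²) denominator, F = W·(ν − q + 1)/(νq) with ν = subjects −
arms, which is exact on complete balanced data; a residual-df variant is
available. The Hotelling default was chosen because the plain Wald/q
approximation is anticonservative at this sample size (its null rejection
rate would sit near 0.10 rather than 0.05).

Sensitivity and item-level models. The LOCF sensitivity analysis is the
two-timepoint group × time model with baseline severity and sessions
completed as covariates, fitted through its algebraic equivalent: OLS of the
baseline-to-week-6 change on group plus the two covariates, reporting the
group F(1, n − 4). The item-level analysis fits the same two-timepoint
contrast per Ham-D item without covariates, F(1, n − 2), reports all 17 rows
with uncorrected p-values and flags p < 0.05, marking explicitly that no
multiplicity correction is applied. Summary-statistic utilities
(pooled-variance t from group summaries, Pearson r with the t-transform p,
percent reduction, Cohen's d as mean difference over pooled SD) mirror the
formulas behind the published secondary analyses.

## Simulation studies and their scope

The acceptance studies run at these problem sizes: parameter recovery uses
500 replicates of complete 200-per-arm cohorts (the configured week-6
contrast of 3.87 points is recovered with |bias| ≤ 0.15 and ~95% CI
coverage); null calibration uses 500 replicates at the trial's own size
(26/25, and 51 with adherence for the sensitivity test), with both tests'
type-I error required to land in [0.03, 0.07] at α = 0.05; the oracle
equivalences use 16-subject datasets.

What passing these studies shows: the estimation and testing machinery is
unbiased and calibrated *under the generator's own assumptions* — normal
residuals with a common covariance, missingness driven by adherence
independently of outcomes (MCAR), arm curves of the configured shape. What
it does not show: robustness to informative dropout, non-normal or
heteroscedastic symptom scores, rater effects, or any claim about real
patients. The generator exists so every analysis stage is testable without
data collection, not as a disease model.

## Known limitations

- The generator's rounding and floor/ceiling at the instrument bounds
  introduce a small (< 0.1 point) truncation bias in extreme cells; it is
  visible only beyond the tolerances used here.
- The within-participant covariance is generated compound-symmetric even
  though the analysis estimates all 28 parameters of an unstructured matrix;
  generating from a richer matrix only changes efficiency, not validity.
- Degrees-of-freedom conventions for MMRM contrasts vary across software;
  both conventions implemented here are recorded in the output, and neither
  is claimed to be the one behind any particular published table.
- The per-arm split of outcome-visit raters implied by some published
  helpfulness t-tests is not recoverable and is not modelled; Likert ratings
  are simulated only to exercise the t-test pathway.
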