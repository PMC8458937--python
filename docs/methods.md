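# Methods

## Model structure

The model couples a per-round diagnostic layer to an annual-cycle Markov
cohort simulation.

**Screening layer.** Each attended round splits the screened cohort by
prevalence p, sensitivity s and specificity σ into true positives (p·s),
false negatives (p·(1−s)), false positives ((1−p)·(1−σ)) and true
negatives. MRM specificity is round-dependent: 92% in the first attended
round, 97% from the second onward, reflecting the availability of prior
examinations for comparison. XM false positives always proceed to biopsy
($1,536); MRM false positives are biopsied at a round-dependent rate
(67.2% in round 1, 80.2% later) and otherwise receive a follow-up MRM
examination, costed at the MRM tariff ($314) because no separate
follow-up price is published. Every false positive carries a 0.01 QOL
decrement for one annual cycle; women with a false positive remain in the
healthy state, with workup cost and disutility accrued as cycle
modifiers, since the state diagram has no false-positive state.

**Markov layer.** Eight reported states: healthy, undetected tumor, three
detected stages (small < 1 cm, large > 1 cm, advanced), post-simple and
post-intensive treatment, and dead (absorbing). Cycle length one year,
horizon 20 years, screening at cycles 0, 2, …, 18 (ten rounds); women in
detected or post-treatment states are no longer screened. Internally the
undetected and post-treatment states are expanded into dwell/tunnel
sub-states so that stage-at-detection and the excess-mortality clock are
exact Markov dynamics; the expansion is collapsed to the eight states for
reporting. Cohort mass is checked to 1e−10 every cycle.

Within a cycle the order of events is: screening (or symptomatic
interval detection) at the cycle start; accrual of screening costs (for
healthy/undetected attendees), expected false-positive workup, one-time
treatment costs for every entry into a detected state, and state
utilities; then the annual transition (incidence, deaths, detected →
post-treatment moves). Costs and QALYs accrue at the post-event state and
are discounted by (1.03)^−t with cycle 0 undiscounted; no half-cycle
correction is applied (deliberately — the closed-form annuity checks in
the test suite rely on start-of-cycle accounting).

**Disease process.** Healthy women acquire undetected tumors at the
age-specific incidence rate. Undetected tumors carry an excess death risk
annualised from 10% over 10 years (1 − 0.9^(1/10) ≈ 1.048%/year).
Detected-stage excess risks are 0.11%, 0.78% and 1.81% per year for
small, large and advanced disease. All excess risks combine with
age-specific all-cause mortality q as competing risks, 1 − (1 − q)(1 −
e), which keeps probabilities in range and is order-independent. Small
tumors are always resected R0 and node-negative, hence proceed to simple
treatment; large tumors reach intensive treatment with probability 0.9
(R0 resection) and otherwise progress to the advanced state, where a
second (advanced) treatment charge applies on entry; advanced disease
proceeds to intensive treatment. Treatment costs ($60,637 / $82,121 /
$129,387) are charged once, on entry into the detected state, at that
cycle's discount factor; the treatment year uses the detected-state
utility (0.87 / 0.74 / 0.62) before the post-treatment utilities (0.99 /
0.95) take over. Post-treatment states carry no recurrence.

## Calibrated structural quantities

The published input tables fix every rate, cost and utility but leave
three structural quantities implicit. They are calibrated by exhaustive
deterministic grid search (252 candidates) against six benchmark outputs
— the base-case cumulative discounted costs and effects of both
strategies and the incremental ratio at later-round specificities of 92%
and 99% — minimising an equally weighted sum of squared relative errors.
Ties break toward the lexicographically smallest candidate, and residuals
are always reported rather than silently accepted. The calibrated values
are the package defaults (`ModelStructure()`):

- **Dwell-time staging**: tumors are detected small when missed at fewer
  than 3 prior rounds, large at 3, advanced from 4 missed rounds on.
  The grid frees both thresholds as a single categorical axis; fixing
  the small→large boundary at one missed round (the most aggressive
  staging) makes the XM arm carry so much late-stage treatment cost that
  MRM would strictly dominate, contradicting every benchmark.
- **Symptomatic interval detection**: 25% per year. Between screens an
  undetected tumor surfaces clinically with this probability and is
  staged advanced. Values of this magnitude are consistent with
  mammographically missed cancers typically presenting within one to two
  years.
- **Excess-mortality duration**: 3 years from detection, after which
  survivors revert to all-cause mortality alone. The annualised
  stage-specific excess rates are highest early after diagnosis, so a
  short window is plausible; the duration is an explicit knob.

The false-positive disutility duration stays at the minimal one cycle and
is not a calibration axis. Achieved residuals: strategy costs +8.3/+8.6%,
effects −4.8%, sweep-endpoint ICERs −4.1%/+5.3% (loss 0.023); the
resulting base-case ICER is within 3% of the benchmark. Note the absolute
QALY scale of the benchmarks (≈ 15.1 of a maximal 15.32 discounted
annuity) is not attainable under genuine US life-table mortality, which
by itself removes ≈ 0.9 discounted QALYs over ages 55–75; the model keeps
real all-cause mortality and reproduces the benchmarks' incremental
structure instead.

## Rate tables

Packaged fixtures cover ages 55–75: female breast-cancer incidence
(annual probability ≈ 0.0025 at 55 rising to ≈ 0.0046 at 75) emulating
the 2017 SEER age-specific rates, and all-cause female mortality
(≈ 0.0042 rising to ≈ 0.0235) emulating the 2017 US life tables. Both are
transcribed approximations of the public sources, as stated in their
header comments, not verbatim copies. Ages outside a table raise rather
than extrapolate. The synthetic generator produces structurally valid
pairs — linear-trend incidence and Gompertz-type (exponential-in-age)
mortality with optional multiplicative Gaussian noise, clipped to [0, 1]
— so every property of the engine can be exercised without any shipped
data.

## Sensitivity analyses

**Tornado.** One parameter at a time is set to the ends of its range with
everything else at base, both strategies re-run, and the signed
incremental ratio recorded; bars are sorted by span. Default ranges:
diagnostic costs ±25%; MRM specificities over the printed
first-to-second-round window [0.92, 0.97]; other performance
probabilities ±10% relative — applied to the false-positive rate
(1 − σ) for specificities, since that is the operative estimated
quantity (a ±10% swing on σ itself would imply an implausible nine-point
absolute change for XM and dwarf every other bar). All ranges are
overridable.

**Two-way surface and break-even.** The surface varies the MRM tariff
and later-round specificity jointly, holding round-1 specificity at 92%.
Break-even solves for the tariff at which cumulative discounted costs of
the two strategies are equal — incremental cost is monotone in the
tariff, so a bracketing root-finder (Brent, $0.01 tolerance) applies; a
bracket without a sign change raises with diagnostic bounds.

**Probabilistic SA.** Each iteration draws every probability and utility
from a beta distribution and every cost from a gamma distribution,
moment-matched to the base value with coefficients of variation 0.1 and
0.2 respectively (configurable per parameter). Parameters at the domain
boundary (e.g. utilities of exactly 1, probabilities of 0) are degenerate
point masses; beta variances are capped just inside the feasible region.
Draws use a single seeded generator in a fixed parameter order, so runs
are bit-reproducible and independent of the internal batch size. The
engine propagates all draws through one vectorised code path (batched
transition matrices, chunked to bound memory); 30,000 iterations of both
strategies take a few seconds on one CPU. The CEAC reports, per
willingness-to-pay value, the fraction of iterations with positive
incremental net monetary benefit; at λ = 0 this equals the fraction in
which MRM is cheaper, and as λ → ∞ it approaches the fraction with a
positive incremental effect.

## What the synthetic inputs do and do not show

The packaged rate fixtures and the synthetic generator reproduce the
*structure* of the public reference tables (magnitudes, monotone
age-increasing mortality, a rising incidence profile), not their exact
published figures, and the calibration absorbs residual differences such
as whether incidence should be conditioned on negative prior screens.
Passing tests therefore demonstrate internal consistency and faithful
reproduction of the benchmark evaluation's decision structure; they do
not constitute an independent epidemiological validation of screening
policy, nor do the PSA distribution families claim to match whatever
distributions produced the published uncertainty figures (they follow
standard practice and reproduce those figures within a few percentage
points).

## Known limitations

- Deterministic cohort model: no individual-level variability, no
  microsimulation, no tumor growth in continuous time, no DCIS/invasive
  distinction.
- 100% screening attendance; no recall tiers beyond the single workup
  step; no radiologist variability.
- Interval-detected cancers are always staged advanced — a deliberately
  coarse single-parameter channel.
- No recurrence after treatment; nodal status enters only through the
  intensive-treatment pathway.
- Costs are US tariffs without inflation adjustment or currency
  conversion; costs and effects share one discount rate.
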