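# Methods

## Decision problem and perspective

The package evaluates a provider-to-provider phone-consultation platform
against the status quo (direct in-person referral) from the healthcare-payer
perspective: only fees the insurer pays enter the model. Patient travel and
time, productivity, and downstream clinical outcomes (QALYs) are out of
scope by design — the evaluation is a cost-benefit analysis in dollars, not
a cost-effectiveness analysis.

## Cost model

Implementation cost is a ledger: at month 0, a one-off onboarding fee per
specialist group (default mean $1,265, SD $230, gamma-distributed in the
generator); at months 1..H, a flat monthly license fee (default $10,000).
An annual opportunity cost of capital r (default 7 %) is applied to the
ongoing fees by monthly compounding, discount factor d = (1 + r)^(−1/12)
applied as d^m at month m; onboarding at month 0 is not discounted.
Discounting is config-switchable because sources that state "a 7 %
opportunity cost of capital was included" rarely state the compounding
convention; monthly compounding of ongoing fees is the standard choice.

The published aggregate cost mean ($145,020) cannot be decomposed into a
unique (groups, months) timeline from published inputs, so the default
ledger is a calibration chosen once: 16 specialist groups and 13 license
months, giving a deterministic discounted total of ≈ $144,958 (within 0.05 %
of the aggregate mean). Where the aggregate mean and its CI are themselves
the input — the reference-case PSA — they are used directly and the ledger
plays no role.

## Benefit model

Per specialty s: avoided(s) = consults(s) × p, where p is the survey-based
avoidance proportion, and benefit = Σ_s avoided(s) × net(s), with net(s) the
comprehensive consultation fee of s minus the phone-encounter cost
(11.5 + 25 MSU at $2.68/MSU = $97.82). Avoided counts are kept unrounded in
all monetary arithmetic and rounded half-up only at display; money is
integer cents internally, so net benefit and the fee identities are exact.
0.84 × 6,072 = 5,100.48 averted referrals rounds to 5,100; published
evaluations of this design sometimes print 5,101 (per-specialty rounding
before summation produces off-by-one differences), and the package treats
agreement within ±1 referral as equivalent.

Per-specialty comprehensive fees are a required input; provincial fee
manuals are not bundled. The generator's default fee mean, $174.17, is a
derived calibration — it is the value that makes the default end-to-end
benefit (≈ $389.4k) consistent with the aggregate benefit mean at p = 0.84 —
not an observed fee. Its dispersion (default SD 0) has no data anchor and is
a free parameter; sampled fees are truncated below at the encounter cost so
net savings stay non-negative (a negative net saving is allowed in the fee
model itself, but warned about).

## Survey estimation

All survey outputs are descriptive: proportions with binomial standard
error √(p(1−p)/n), no weighting, no tests. "Satisfied or very satisfied"
and "agree or strongly agree" are both operationalized as top-two-box
(Likert ≥ 4). Not-applicable and missing answers are excluded from each
item's denominator and reported separately, since each published percentage
carries its own denominator. The 4-level referral-necessity item admits a
declined/absent state; its breakdown reports unnecessary-ish, necessary-ish
and residual shares over all submitted responses, which therefore sum to 1.

## Probabilistic sensitivity analysis

Each named model input gets a distribution: gamma for costs and counts
(method of moments: shape (m/s)², scale s²/m), beta for proportions
(ν = m(1−m)/s² − 1), or a point mass. SD precedence: stated SD, then
CI-derived (hi − lo)/3.92, then the 10 %-of-mean rule; proportions with a
known denominator use the binomial SE rather than the 10 % rule. Inputs are
sampled independently — no correlation structure is asserted.

1000 draws per run (Monte Carlo SE of the mean ROI ≈ 0.02 under the
reference calibration). Per draw, the model maps sampled inputs to total
benefit and cost, and the engine derives net benefit, BCR and ROI; summaries
are means over draws with percentile 2.5/97.5 intervals (linear
interpolation between order statistics). Headline ratio metrics are
means of per-draw ratios; by Jensen's inequality these exceed the
ratio-of-means point estimates (2.78 vs 2.69 for the BCR under the reference
calibration), and the deterministic engine reports the latter so both
conventions are visible. The one-way scenario multiplies every sampled cost
by a factor (default 2) after sampling, on the same per-quantity substreams,
so scenario and reference case differ only in the multiplier.

Randomness: each named quantity draws from its own substream derived from
the master seed (SeedSequence spawn keyed by a CRC-32 of the quantity name),
so adding a quantity to a spec never perturbs the draws of existing ones and
every run is bit-reproducible given (spec, seed).

## Synthetic data: what it does and does not emulate

The generator reproduces the study conditions as first-class defaults:
6,072 completed consults multinomially distributed over the top-ten
specialty counts with the remainder pooled as "other"; 873 primary-care and
143 specialist providers; 608 primary-care and 653 specialist
post-consultation responses sampled without replacement from the consult log
(preserving the consult↔response linkage of a per-consult pop-up survey)
with avoidance Bernoulli(0.84), satisfaction top-two rates 0.99/0.96,
necessity split (0.55, 0.40, 0.05 declined), follow-up rates (0.89, 0.89,
0.90) among non-avoided; 89 experience responses with usage-band weights
(34, 20, 18, 17) and the reported top-two impact rates.

It does not emulate: temporal growth in uptake (dates are uniform over the
window), provider-level clustering of consults and responses, non-response
bias (responders are a uniform random subset), seasonal case mix, or
free-text content. Parameter-recovery tests on this generator therefore
show that the estimators are correct and calibrated, not that the real
surveys were unbiased.

## Numerical choices

- Money: integer cents; round-half-up at each published-figure boundary
  (display: whole dollars for money, one decimal for ratios, whole or
  1-decimal percent mirroring the two table conventions).
- Tally ordering: descending count, ties alphabetical (deterministic
  reports).
- Utilization vs economics study windows are config filters, not hard-coded;
  the default pipeline uses the full generated window for both so the
  benefit arithmetic matches the consult total.
- Degenerate inputs: empty consult logs tally to empty lists; an empty
  provider registry has undefined (absent) shares; ratio metrics at zero
  cost are reported as undefined rather than infinite; a PSA with all point
  distributions collapses to the deterministic result.

## Problem sizes

Default runs are desk-scale: 6,072-consult datasets, 1000-draw PSAs, and
10⁵-draw moment-recovery checks, all completing in seconds.

## Known limitations

Single currency-year (2022 CAD) with no inflation adjustment or currency
conversion; no QALY-based outcomes; benefits and costs sampled
independently; the cost-timeline calibration is one of many decompositions
consistent with the aggregate mean; survey percentages whose raw counts are
not published are covered by parameter-recovery properties rather than exact
reproduction.
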