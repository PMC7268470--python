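# Methods

## Model and assumptions

The package treats augmentation of a registry cohort as a measurement-error
problem. A binary behaviour X with prevalence p is never observed on the
cohort; instead each case receives two values X₁, X₂ imputed by random
cold-deck draws from a survey stratified on shared demographics. The working
model for a pair of imputations of the same case is an exchangeable 2×2 joint
law

    P11 = p² + p(1−p)ρ,   P10 = P01 = p(1−p)(1−ρ),   P00 = (1−p)² + p(1−p)ρ,

i.e. chance agreement plus an excess-match term p(1−p)ρ, with ρ equal to the
phi coefficient (the Pearson correlation of the 0/1 pair). Under this model,
and assuming behaviour prevalence is common to donors and cases within
strata and misclassification is non-differential with respect to the
outcome, a true risk ratio RR_T between behaviour and one-year death appears
on the imputed scale as

    RR_i = 1 + (RR_T − 1)·ρ / [1 + (RR_T − 1)·p·(1 − ρ)],

which the estimator inverts:

    RR_T = 1 − (RR_i − 1) / [(RR_i − 1)·p·(1 − ρ) − ρ].

The inversion is exact algebra, but it divides by a quantity of order ρ:
when ρ is small, sampling noise in RR_i routinely flips the sign of the
denominator or the numerator and the corrected value lands below zero. Such
draws are recorded as **impossible** rather than patched; if more than 5%
(strict inequality) of non-invalid repetitions are impossible, the
behaviour's imputation is reported as **failed** with sentinel cells in the
results table. This is the intended behaviour of the method: a failed label
is the signal that the auxiliary variables carry too little information
about that behaviour.

## Imputation procedure

Donor strata are keyed on (age band − `age_group_shift`, gender, marital
status, race, region, year − `lag_years`); defaults shift one five-year age
band and five calendar years, so donors describe behaviour well before
diagnosis. Within a stratum, donors are assigned by uniform sampling without
replacement — each donor serves at most one recipient per behaviour per
repetition, and each recipient consumes two distinct donors. Recipients are
processed in a random permutation within the stratum so that, when donors
run out, which recipients are excluded is exchangeable rather than
input-order dependent. Exclusions are counted in two classes: donor
exhaustion, and no donor stratum at all (which includes recipients already
in the youngest age band, for whom the shifted band does not exist). The
donor pool is restored between repetitions: repetitions are independent
replicates of the algorithm, not a progressive depletion.

Each behaviour uses its own complete-case donor dataset (donors missing that
behaviour are dropped for that behaviour only), so missingness in one
behaviour never contaminates another and a missing value is never imputed
into a recipient.

## Estimation choices

- Prevalence p̂ is pooled over both imputed vectors ((Σx₁+Σx₂)/2n) —
  identical to averaging the two per-vector rates.
- The crude RR cross-tabulates the *first* imputed value against death; the
  two draws are exchangeable, so the choice is conventional.
- Age adjustment uses the Mantel–Haenszel pooled risk ratio
  Σₖ aₖn₀ₖ/Nₖ / Σₖ bₖn₁ₖ/Nₖ. It is written in-package (four-line sums)
  because the contract requires strata with an empty exposure group to
  contribute zero to both sums and a flagged NaN on a zero denominator;
  tests verify equality with `statsmodels`' pooled estimator on non-degenerate
  fixtures.
- The same overall (p̂, ρ̂) corrects both the crude and the age-adjusted RR,
  consistent with the equal-prevalence-across-strata premise of the
  correction formula; per-stratum calibration would demand far more donors
  per stratum than the design provides.
- Undefined statistics (degenerate phi margin, empty exposure group, no
  unexposed deaths) invalidate that repetition for that estimand; no
  continuity corrections are applied. Invalid repetitions are excluded from
  medians and intervals and are tracked separately from impossible ones;
  only impossible results feed the failed rule.

## Repetition summaries

Medians and the 2.5th/97.5th percentiles are computed over valid draws with
linear interpolation on the (n+1)·q plotting position (`numpy`'s "weibull"
rule), so with 100 repetitions the 2.5th percentile interpolates between the
2nd and 3rd order statistics. Randomness is organised as one master seed
from which every (behaviour, repetition, purpose) derives an independent
substream via `numpy.random.SeedSequence`; results are therefore
bit-reproducible and independent of execution order.

## Survival simulation

The validation study designates the first imputed value as the true
behaviour and draws deaths independently with baseline risk
R0 = d / (1 + p̂(RR − 1)) for unexposed and R1 = RR·R0 for exposed, where p̂
is the *empirical* prevalence of the truth vector — conditioning on p̂ keeps
the realised RR centred on the target regardless of sampling noise in the
truth draw, and keeps the overall death rate at d by construction. A
Bernoulli draw per subject is used (an assumption; a deterministic quota
assignment would also preserve the margins but would understate binomial
variation). When max(R0, R1) > 1 no pair of risks in [0, 1] can realise the
target and the (behaviour, target) cell is reported `Not possible`; for
targets ≥ 1 the binding constraint is R1 = RR·d/(1 + p(RR − 1)) ≤ 1, while
for targets < 1 the baseline risk R0 can bind instead at large d and p.

The default overall one-year death rate is **d = 0.54**. The attenuation and
its correction are invariant to d (the baseline risk cancels in the risk
ratio — a property the test suite checks); d only moves the feasibility
boundary, and 0.54 places that boundary so that a target RR of 2.00 is
unachievable below roughly 8% prevalence, matching the behaviour of
low-prevalence exposures in this setting. d is a parameter of every
simulation entry point.

## Synthetic data

`generate_donor_pool` / `generate_recipient_cohort` emulate the two tables
with exact per-stratum counts, configurable per-stratum behaviour
prevalences, and completely-at-random missingness; `generate_correlated_pairs`
draws i.i.d. pairs from the 2×2 law above and is the fixture for everything
downstream of imputation. None of this models survey sampling weights,
design effects, nonresponse, or realistic registry age/stage structure —
passing tests demonstrate that the estimator chain is correct under its own
model, not that real survey-to-registry imputation satisfies that model
(equal prevalence across strata and non-differential error are assumptions,
not guarantees, on real data).

Validation studies default to cohort sizes near 28 000 and 100 repetitions,
the scale at which the method is intended to operate; at this size each
study runs in about a second, so no reduced problem sizes are needed
anywhere in the test suite.

## Known limitations

- The correction presumes non-differential misclassification; differential
  error (e.g. behaviour measured differently for survivors) would bias RR_T
  in ways the calibration cannot see.
- Empirical percentile intervals reflect only imputation randomness, not
  sampling uncertainty of the cohort itself.
- The failed rule is a binary gate at 5%; near the boundary, the label can
  flip between otherwise indistinguishable runs.
- Subgroup analyses reuse the overall imputation and re-calibrate within the
  subgroup; very small subgroups can produce degenerate phi margins, which
  surface as invalid repetitions rather than errors.
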