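# colddeck

Cancer-registry datasets record demographics and survival but not
pre-diagnosis health behaviour, and for most registries there is no dataset
with cases in common to link against. `colddeck` augments such a
registry-like cohort with *fully imputed* binary behaviours (smoking, risky
drinking, physical activity, obesity, …) drawn from an unrelated survey-like
dataset, then quantifies — and corrects for — the misclassification this
imputation necessarily introduces when estimating relative risks of one-year
mortality.

## The method

**Random cold-deck imputation.** Recipients (registry cases) and donors
(survey respondents) are stratified on six shared auxiliary variables: age
band, gender, marital status, race, region, and calendar year. A donor
stratum is lagged — `lag_years` (default 5) earlier and one age band younger —
so donors report behaviour as it was *before* the recipient's diagnosis.
Within each stratum every recipient receives **two** donor values drawn
uniformly at random *without replacement*; recipients left without two donors
are excluded and counted, as are recipients whose shifted stratum holds no
donors at all. Each behaviour is imputed independently on its own
complete-case donor dataset.

**Calibration.** With prevalence *p*, two uninformative imputations would
agree "behaviour present" at the chance rate *p*². Informative imputation
produces excess matches, modelled as *p*(1−*p*)·*ρ* per pair, where *ρ* is
estimated by the phi coefficient φ (the Pearson correlation of the two 0/1
vectors). The triple (n, p̂, ρ̂) measures how much information the imputation
carries.

**Correction.** Non-differential misclassification attenuates a risk ratio
toward the null:

    RR_i = 1 + (RR_T − 1)·ρ / [1 + (RR_T − 1)·p·(1 − ρ)]

`colddeck` estimates the crude RR_i (and a Cochran–Mantel–Haenszel
age-adjusted adjRR_i) from the first imputed value against one-year death,
then inverts the attenuation:

    RR_T = 1 − (RR_i − 1) / [(RR_i − 1)·p·(1 − ρ) − ρ]

A corrected value below zero is an *impossible* result; if more than 5% of
repetitions are impossible the behaviour's imputation is labelled **failed**.

**Repetition engine.** Because donors are drawn at random, the whole pipeline
is repeated (default 100 times) and every statistic is reported as the median
with the 2.5th/97.5th empirical percentiles as a 95% interval.

**Validation by simulation.** The first imputed value is designated the true
behaviour; one-year deaths are simulated at target relative risks
(0.50–2.00) while preserving the overall death rate; the second imputed value
plays the imputed exposure. Recovering the target through the correction
validates the whole chain. Targets whose required exposed-group risk exceeds
1 are reported as `Not possible`.

## Worked example

Run the validation study at a typical smoking calibration (n = 27 835,
p = 0.159, ρ = 0.071) with a target relative risk of 2.00 and an overall
one-year death rate of 0.54:

```python
from colddeck import StudyConfig, validate_pairs_study

cfg = StudyConfig(behaviours=("smoking",), repetitions=100, seed=1)
study = validate_pairs_study("smoking", n=27_835, p=0.159, rho=0.071,
                             config=cfg, targets=(2.0,), death_rate=0.54)
for s in study.summaries:
    print(f"{s.estimand:>14}  median={s.median:.3f}  "
          f"95% CI=({s.lower:.3f}, {s.upper:.3f})")
```

prints

```
         p_hat  median=0.159  95% CI=(0.155, 0.162)
       rho_hat  median=0.070  95% CI=(0.058, 0.085)
excess_matches  median=260.349  95% CI=(214.488, 317.634)
        rr_sim  median=2.002  95% CI=(1.967, 2.032)
          rr_i  median=1.060  95% CI=(1.035, 1.092)
          rr_t  median=1.987  95% CI=(1.521, 2.464)
```

Read: the simulated data realised the target RR of 2.00 almost exactly
(`rr_sim`); the imputed exposure sees only a heavily attenuated 1.06
(`rr_i`) because the imputation is only weakly informative (ρ̂ ≈ 0.07,
about 260 agreements beyond chance among 27 835 pairs); inverting the
attenuation recovers the true effect (`rr_t` ≈ 2.0), at the price of a wide
empirical confidence interval.

The same pipeline runs from the command line on CSV tables — see
`colddeck --help` for the `synth`, `impute`, `calibrate`, `estimate`,
`validate` and `report` subcommands. Every run writes a `manifest.json`
(config snapshot, seed, input digests) from which it can be reproduced
exactly.

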