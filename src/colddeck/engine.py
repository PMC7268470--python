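"""Repetition engine: run the stochastic imputation pipeline many times and
summarise each estimand by its median and empirical percentile interval.

Because donors are drawn at random within strata, every statistic varies
between repetitions. Each of the ``repetitions`` (default 100) re-runs the
double imputation with an independent substream, recomputes calibration and
relative risks, and the engine reports the median with the 2.5th/97.5th
empirical percentiles as a 95% interval. Corrected relative risks that land
below zero are *impossible*; when more than ``failure_threshold`` of
repetitions are impossible the behaviour's imputation is labelled failed.

The same engine drives the simulation validation study: the first imputed
value is designated the true behaviour, survival is simulated at each target
relative risk, and the corrected estimate from the second imputed value is
compared against the target.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CalibrationResult, calibrate_pairs
from .estimation import cmh_rr, correct_rr, crude_rr
from .imputation import build_donor_datasets, impute_double
from .model import (
    CORRECTED_ESTIMANDS,
    OVERALL_SUBGROUP,
    STATUS_SERVED,
    SUBGROUP_COLUMN,
    RepetitionSummary,
    StudyConfig,
)
from .synthetic import (
    DEFAULT_TARGET_GRID,
    SimulationSpec,
    generate_correlated_pairs,
    simulate_survival,
)

logger = logging.getLogger("colddeck")

#: Default overall one-year death rate for simulation studies.
DEFAULT_DEATH_RATE = 0.54

_DRAW_COLUMNS = (
    "behaviour",
    "subgroup",
    "target_rr",
    "repetition",
    "estimand",
    "value",
    "impossible",
    "invalid",
    "n",
)

_SIM_ESTIMANDS = ("rr_sim", "rr_i", "rr_t")
_CALIB_ESTIMANDS = ("p_hat", "rho_hat", "excess_matches")


def _token(t) -> int:
    if isinstance(t, (int, np.integer)) and t >= 0:
        return int(t)
    return zlib.crc32(repr(t).encode())


def child_rng(seed: int, *tokens) -> np.random.Generator:
    """Independent, order-insensitive random substream keyed by tokens.

    Identical (seed, tokens) always yields the same stream, so repetitions
    are reproducible regardless of execution order.
    """
    entropy = [int(seed)] + [_token(t) for t in tokens]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def summarize(
    values,
    impossible=None,
    invalid=None,
    *,
    estimand: str,
    config: StudyConfig,
    behaviour: str = "",
    subgroup: str = OVERALL_SUBGROUP,
    n: int = 0,
    target_rr: float | None = None,
) -> RepetitionSummary:
    """Median and empirical percentile interval over the valid draws.

    Impossible and invalid draws are excluded from the median and interval;
    the failed rule (strictly more than ``failure_threshold`` impossible
    among non-invalid repetitions) applies only to corrected estimands.
    Percentiles interpolate linearly on the (n+1)·q plotting position, so
    with 100 draws the 2.5th percentile lies between the 2nd and 3rd order
    statistics.
    """
    values = np.asarray(values, dtype=float)
    if impossible is None:
        impossible = np.zeros(values.size, dtype=bool)
    else:
        impossible = np.asarray(impossible, dtype=bool)
    if invalid is None:
        invalid = np.zeros(values.size, dtype=bool)
    else:
        invalid = np.asarray(invalid, dtype=bool)
    kept = values[np.isfinite(values) & ~impossible & ~invalid]
    impossible_count = int(impossible.sum())
    invalid_count = int(invalid.sum())
    if kept.size:
        lo, hi = config.ci_percentiles
        lower, median, upper = np.quantile(
            kept, [lo / 100.0, 0.5, hi / 100.0], method="weibull"
        )
    else:
        lower = median = upper = float("nan")
    failed = False
    if estimand in CORRECTED_ESTIMANDS:
        denom = values.size - invalid_count
        failed = denom <= 0 or impossible_count > config.failure_threshold * denom
    return RepetitionSummary(
        behaviour=behaviour,
        subgroup=subgroup,
        estimand=estimand,
        n=int(n),
        median=float(median),
        lower=float(lower),
        upper=float(upper),
        impossible_count=impossible_count,
        invalid_count=invalid_count,
        failed=failed,
        target_rr=target_rr,
    )


@dataclass
class StudyResult:
    """Summaries plus the per-repetition sidecar of raw draws."""

    summaries: list[RepetitionSummary] = field(default_factory=list)
    draws: pd.DataFrame = field(default_factory=pd.DataFrame)


def _record(records, behaviour, subgroup, target, rep, estimand, value, n,
            impossible=False, invalid=False):
    records.append(
        {
            "behaviour": behaviour,
            "subgroup": subgroup,
            "target_rr": target,
            "repetition": rep,
            "estimand": estimand,
            "value": value,
            "impossible": bool(impossible),
            "invalid": bool(invalid),
            "n": n,
        }
    )


def _calibration_records(records, behaviour, subgroup, rep, calib, n, target=None):
    bad = not calib.valid
    _record(records, behaviour, subgroup, target, rep, "p_hat", calib.p_hat, n)
    _record(
        records, behaviour, subgroup, target, rep, "rho_hat", calib.rho_hat, n,
        invalid=bad,
    )
    _record(
        records, behaviour, subgroup, target, rep, "excess_matches",
        calib.excess_matches, n, invalid=bad,
    )


def _summaries_from_records(records, config) -> StudyResult:
    draws = pd.DataFrame(records, columns=_DRAW_COLUMNS)
    summaries = []
    if len(draws) == 0:
        return StudyResult(summaries=summaries, draws=draws)
    grouped = draws.groupby(
        ["behaviour", "subgroup", "target_rr", "estimand"], dropna=False, sort=False
    )
    for (b, g, t, e), grp in grouped:
        summaries.append(
            summarize(
                grp["value"].to_numpy(dtype=float),
                grp["impossible"].to_numpy(),
                grp["invalid"].to_numpy(),
                estimand=e,
                config=config,
                behaviour=b,
                subgroup=g,
                n=int(np.median(grp["n"])) if len(grp) else 0,
                target_rr=None if pd.isna(t) else float(t),
            )
        )
    return StudyResult(summaries=summaries, draws=draws)


def _subgroup_labels(recipients: pd.DataFrame) -> list[str]:
    groups = [OVERALL_SUBGROUP]
    if SUBGROUP_COLUMN in recipients.columns:
        groups += sorted(recipients[SUBGROUP_COLUMN].dropna().unique().tolist())
    return groups


def run_study(
    recipients: pd.DataFrame, donors: pd.DataFrame, config: StudyConfig
) -> StudyResult:
    """Full study on observed outcomes: calibration plus crude and
    age-adjusted relative risks, corrected for misclassification, summarised
    over repetitions for the whole cohort and each subgroup."""
    datasets = build_donor_datasets(donors, config.behaviours)
    groups = _subgroup_labels(recipients)
    rec_cols = ["id", "age_group", "death_within_1yr"]
    if SUBGROUP_COLUMN in recipients.columns:
        rec_cols.append(SUBGROUP_COLUMN)
    records: list[dict] = []
    for b in config.behaviours:
        for rep in range(config.repetitions):
            rng = child_rng(config.seed, b, rep, "impute")
            assign = impute_double(recipients, datasets[b], b, config, rng)
            merged = assign.merge(recipients[rec_cols], on="id", how="left")
            served = merged[
                (merged["status"] == STATUS_SERVED)
                & merged["death_within_1yr"].notna()
            ]
            logger.info(
                "behaviour=%s repetition=%d served=%d excluded=%d",
                b, rep, len(served), len(merged) - len(served),
            )
            for g in groups:
                sub = (
                    served
                    if g == OVERALL_SUBGROUP
                    else served[served[SUBGROUP_COLUMN] == g]
                )
                if len(sub) == 0:
                    continue
                v1 = sub["value_1"].to_numpy(dtype=np.int64)
                v2 = sub["value_2"].to_numpy(dtype=np.int64)
                death = sub["death_within_1yr"].to_numpy(dtype=np.int64)
                age = sub["age_group"].to_numpy(dtype=object)
                calib = calibrate_pairs(v1, v2)
                n = len(sub)
                _calibration_records(records, b, g, rep, calib, n)
                rr_i = crude_rr(v1, death)
                adj_rr_i = cmh_rr(v1, death, age)
                if calib.valid:
                    rr_t, imp_c = correct_rr(rr_i, calib.p_hat, calib.rho_hat)
                    adj_rr_t, imp_a = correct_rr(adj_rr_i, calib.p_hat, calib.rho_hat)
                else:
                    rr_t, imp_c = float("nan"), False
                    adj_rr_t, imp_a = float("nan"), False
                _record(records, b, g, None, rep, "rr_i", rr_i, n,
                        invalid=not np.isfinite(rr_i))
                _record(records, b, g, None, rep, "adj_rr_i", adj_rr_i, n,
                        invalid=not np.isfinite(adj_rr_i))
                _record(records, b, g, None, rep, "rr_t", rr_t, n,
                        impossible=imp_c,
                        invalid=not np.isfinite(rr_t) and not imp_c)
                _record(records, b, g, None, rep, "adj_rr_t", adj_rr_t, n,
                        impossible=imp_a,
                        invalid=not np.isfinite(adj_rr_t) and not imp_a)
    result = _summaries_from_records(records, config)
    _warn_empty(result, config)
    return result


def run_calibration(
    recipients: pd.DataFrame, donors: pd.DataFrame, config: StudyConfig
) -> StudyResult:
    """Calibration-only study: p̂, ρ̂ and excess matches per behaviour.

    Does not require an outcome column, so it can audit the information
    content of an imputation before any survival analysis.
    """
    datasets = build_donor_datasets(donors, config.behaviours)
    records: list[dict] = []
    for b in config.behaviours:
        for rep in range(config.repetitions):
            rng = child_rng(config.seed, b, rep, "impute")
            assign = impute_double(recipients, datasets[b], b, config, rng)
            served = assign[assign["status"] == STATUS_SERVED]
            if len(served) == 0:
                continue
            calib = calibrate_pairs(
                served["value_1"].to_numpy(dtype=np.int64),
                served["value_2"].to_numpy(dtype=np.int64),
            )
            _calibration_records(
                records, b, OVERALL_SUBGROUP, rep, calib, len(served)
            )
    return _summaries_from_records(records, config)


def _simulation_target_records(
    records, not_possible, behaviour, rep, v1, v2, calib, targets, death_rate,
    rng_factory,
):
    """Per-repetition simulation draws for every feasible target RR."""
    n = v1.size
    for ti, target in enumerate(targets):
        if not_possible.get(target, False):
            continue
        spec = SimulationSpec(
            target_rr=float(target),
            death_rate=float(death_rate),
            prevalence=min(max(float(v1.mean()), 0.0), 1.0),
            n=max(n, 1),
        )
        try:
            death = simulate_survival(v1, spec, rng_factory(ti))
        except ValueError:
            not_possible[target] = True
            continue
        rr_sim = crude_rr(v1, death)
        rr_i = crude_rr(v2, death)
        if calib.valid:
            rr_t, imp = correct_rr(rr_i, calib.p_hat, calib.rho_hat)
        else:
            rr_t, imp = float("nan"), False
        _record(records, behaviour, OVERALL_SUBGROUP, target, rep, "rr_sim",
                rr_sim, n, invalid=not np.isfinite(rr_sim))
        _record(records, behaviour, OVERALL_SUBGROUP, target, rep, "rr_i",
                rr_i, n, invalid=not np.isfinite(rr_i))
        _record(records, behaviour, OVERALL_SUBGROUP, target, rep, "rr_t",
                rr_t, n, impossible=imp,
                invalid=not np.isfinite(rr_t) and not imp)


def _not_possible_summaries(not_possible, behaviour, targets):
    """Drop partial draws and emit 'Not possible' rows for infeasible targets."""
    summaries = []
    for target in targets:
        if not not_possible.get(target, False):
            continue
        for estimand in _SIM_ESTIMANDS:
            summaries.append(
                RepetitionSummary(
                    behaviour=behaviour,
                    subgroup=OVERALL_SUBGROUP,
                    estimand=estimand,
                    n=0,
                    median=float("nan"),
                    lower=float("nan"),
                    upper=float("nan"),
                    impossible_count=0,
                    invalid_count=0,
                    failed=False,
                    not_possible=True,
                    target_rr=float(target),
                )
            )
    return summaries


def _finish_simulation(records, not_possible_by_behaviour, targets, config):
    # a target found infeasible in any repetition is reported Not possible
    # for the whole behaviour; purge draws from repetitions made before the
    # infeasibility surfaced
    records = [
        r
        for r in records
        if r["target_rr"] is None
        or not not_possible_by_behaviour[r["behaviour"]].get(r["target_rr"], False)
    ]
    result = _summaries_from_records(records, config)
    for b, np_map in not_possible_by_behaviour.items():
        result.summaries.extend(_not_possible_summaries(np_map, b, targets))
    return result


def run_simulation_study(
    recipients: pd.DataFrame,
    donors: pd.DataFrame,
    config: StudyConfig,
    targets=DEFAULT_TARGET_GRID,
    death_rate: float = DEFAULT_DEATH_RATE,
) -> StudyResult:
    """Validation study on imputed cohorts.

    Per repetition the first imputed value is designated the true behaviour;
    deaths are simulated at each target RR preserving the overall death rate;
    the imputed-scale RR uses the second imputed value and is corrected with
    that repetition's calibration. Infeasible targets are reported as
    'Not possible' rows rather than raising.
    """
    datasets = build_donor_datasets(donors, config.behaviours)
    records: list[dict] = []
    not_possible: dict[str, dict] = {b: {} for b in config.behaviours}
    for b in config.behaviours:
        for rep in range(config.repetitions):
            rng = child_rng(config.seed, b, rep, "impute")
            assign = impute_double(recipients, datasets[b], b, config, rng)
            served = assign[assign["status"] == STATUS_SERVED]
            if len(served) == 0:
                continue
            v1 = served["value_1"].to_numpy(dtype=np.int64)
            v2 = served["value_2"].to_numpy(dtype=np.int64)
            calib = calibrate_pairs(v1, v2)
            _calibration_records(records, b, OVERALL_SUBGROUP, rep, calib, v1.size)
            _simulation_target_records(
                records, not_possible[b], b, rep, v1, v2, calib, targets,
                death_rate,
                lambda ti, _b=b, _r=rep: child_rng(config.seed, _b, _r, "survival", ti),
            )
    return _finish_simulation(records, not_possible, targets, config)


def validate_pairs_study(
    behaviour: str,
    n: int,
    p: float,
    rho: float,
    config: StudyConfig,
    targets=DEFAULT_TARGET_GRID,
    death_rate: float = DEFAULT_DEATH_RATE,
) -> StudyResult:
    """Validation study run directly from correlated imputed pairs.

    Instead of a full donor/recipient imputation, each repetition draws n
    fresh pairs of binary values with prevalence p and phi correlation rho —
    the statistical signature the double imputation leaves on a cohort — and
    then proceeds exactly like :func:`run_simulation_study`. This isolates
    the calibration-and-correction machinery at known (p, ρ).
    """
    records: list[dict] = []
    not_possible: dict[str, dict] = {behaviour: {}}
    for rep in range(config.repetitions):
        v1, v2 = generate_correlated_pairs(
            n, p, rho, child_rng(config.seed, behaviour, rep, "pairs")
        )
        calib = calibrate_pairs(v1, v2)
        _calibration_records(records, behaviour, OVERALL_SUBGROUP, rep, calib, n)
        _simulation_target_records(
            records, not_possible[behaviour], behaviour, rep, v1, v2, calib,
            targets, death_rate,
            lambda ti, _r=rep: child_rng(config.seed, behaviour, _r, "survival", ti),
        )
    return _finish_simulation(records, not_possible, targets, config)


def _warn_empty(result: StudyResult, config: StudyConfig) -> None:
    for b in config.behaviours:
        rows = [s for s in result.summaries if s.behaviour == b]
        if rows and all(np.isnan(s.median) and not s.not_possible for s in rows):
            logger.warning("behaviour %s produced no valid repetitions", b)
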