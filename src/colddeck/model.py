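"""Shared data model: table schemas, missing-value conventions, study configuration.

Two tables flow through the package. The *recipient* table is a registry-like
cohort (one row per case, with demographic auxiliary variables, diagnosis year
and a binary one-year death indicator). The *donor* table is a survey-like pool
(one row per respondent, the same auxiliary variables, survey year, and one
0/1 column per health behaviour, possibly with missing cells).

Both tables are held as pandas DataFrames; this module declares the column
contracts and the single internal missing sentinel (``pandas.NA`` via nullable
integer dtypes).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, Sequence

import yaml

#: Auxiliary variables shared by donor and recipient tables; together with the
#: lag/age-shift transformation they define the imputation strata.
AUX_COLUMNS: tuple[str, ...] = (
    "age_group",
    "gender",
    "marital_status",
    "race",
    "region",
    "year",
)

RECIPIENT_REQUIRED: tuple[str, ...] = ("id", *AUX_COLUMNS, "death_within_1yr")
DONOR_REQUIRED: tuple[str, ...] = ("id", *AUX_COLUMNS)
SUBGROUP_COLUMN = "subgroup"
OVERALL_SUBGROUP = "overall"

#: Five-year age bands from 35-39 up to 75-79 and then an open 80+ band.
DEFAULT_AGE_GROUPS: tuple[str, ...] = (
    "35-39",
    "40-44",
    "45-49",
    "50-54",
    "55-59",
    "60-64",
    "65-69",
    "70-74",
    "75-79",
    "80+",
)

# Imputation status codes for each (recipient, behaviour).
STATUS_SERVED = "served"
STATUS_EXHAUSTED = "donors_exhausted"
STATUS_NO_STRATUM = "no_donor_stratum"

# Sentinels used in the results table, mirroring how the summary tables are
# conventionally printed.
SENTINEL_FAILED = "failed"
SENTINEL_NOT_POSSIBLE = "Not possible"

#: Estimands whose repetition summary is subject to the "failed" rule
#: (misclassification-corrected relative risks).
CORRECTED_ESTIMANDS = frozenset({"rr_t", "adj_rr_t"})

#: All estimand names emitted by the repetition engine.
ESTIMANDS = (
    "p_hat",
    "rho_hat",
    "excess_matches",
    "rr_sim",
    "rr_i",
    "adj_rr_i",
    "rr_t",
    "adj_rr_t",
)


@dataclass(frozen=True)
class StudyConfig:
    """Study-level parameters for imputation, calibration and summarisation.

    Parameters
    ----------
    behaviours
        Names of the binary behaviour columns to impute (each handled
        independently on its own complete-case donor dataset).
    age_groups
        Ordered age bands; ordering is what makes the one-band age shift of
        the donor stratum well defined.
    categories
        Optional mapping column -> allowed category values, used to flag
        unparseable cells as missing on read.
    lag_years
        Donor records must predate the recipient's diagnosis year by this
        many years (behaviour before diagnosis, so early symptoms cannot
        influence it). Default 5.
    age_group_shift
        Donors are this many age bands younger than the recipient, matching
        the calendar lag. Default 1.
    repetitions
        Number of independent re-runs of the random imputation. Default 100.
    seed
        Master seed; every stochastic step derives an independent substream.
    ci_percentiles
        Percentile pair for the empirical interval. Default (2.5, 97.5).
    failure_threshold
        If the fraction of repetitions with an impossible corrected relative
        risk exceeds this (strictly), the behaviour's imputation is labelled
        failed. Default 0.05.
    """

    behaviours: tuple[str, ...]
    age_groups: tuple[str, ...] = DEFAULT_AGE_GROUPS
    categories: Mapping[str, tuple[str, ...]] | None = None
    lag_years: int = 5
    age_group_shift: int = 1
    repetitions: int = 100
    seed: int = 0
    ci_percentiles: tuple[float, float] = (2.5, 97.5)
    failure_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not self.behaviours:
            raise ValueError("at least one behaviour must be declared")
        if len(set(self.behaviours)) != len(self.behaviours):
            raise ValueError("behaviour names must be unique")
        if len(self.age_groups) < 1:
            raise ValueError("age_groups must be non-empty")
        if self.lag_years < 0:
            raise ValueError("lag_years must be >= 0")
        if self.age_group_shift < 0:
            raise ValueError("age_group_shift must be >= 0")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        lo, hi = self.ci_percentiles
        if not (0 < lo < hi < 100):
            raise ValueError("ci_percentiles must be ordered and inside (0, 100)")
        if not (0 < self.failure_threshold < 1):
            raise ValueError("failure_threshold must be in (0, 1)")
        # normalise sequences to tuples so the config is hashable/immutable
        object.__setattr__(self, "behaviours", tuple(self.behaviours))
        object.__setattr__(self, "age_groups", tuple(self.age_groups))
        object.__setattr__(self, "ci_percentiles", tuple(self.ci_percentiles))
        if self.categories is not None:
            object.__setattr__(
                self,
                "categories",
                {k: tuple(v) for k, v in self.categories.items()},
            )

    def replace(self, **changes) -> "StudyConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["behaviours"] = list(self.behaviours)
        d["age_groups"] = list(self.age_groups)
        d["ci_percentiles"] = list(self.ci_percentiles)
        if self.categories is not None:
            d["categories"] = {k: list(v) for k, v in self.categories.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**{k: v for k, v in d.items()})

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config file must hold a key-value mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class RepetitionSummary:
    """Median and empirical percentile interval of one estimand over repetitions.

    ``impossible_count`` counts repetitions whose corrected relative risk was
    negative (or arose from a zero denominator); ``invalid_count`` counts
    repetitions where the statistic itself was undefined (degenerate phi
    margin, empty exposure group, no unexposed deaths). Both are excluded
    from the median and interval; only impossible results feed the failed
    rule. ``not_possible`` marks simulation targets that cannot be realised
    because the required risk in the exposed would exceed 1.
    """

    behaviour: str
    subgroup: str
    estimand: str
    n: int
    median: float
    lower: float
    upper: float
    impossible_count: int
    invalid_count: int
    failed: bool
    not_possible: bool = False
    target_rr: float | None = None
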