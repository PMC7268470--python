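"""Calibration of the imputation from the paired imputed values.

Two independently drawn donor values per recipient allow the information
content of the imputation to be measured. If the imputation carried no
information, value-present/value-present agreement would occur at the chance
rate p². Informative imputation produces excess matches, modelled as
p(1−p)·ρ where ρ is the phi coefficient (the Pearson correlation between the
two 0/1 vectors). The triple (n, p̂, ρ̂) then drives the misclassification
correction of relative risks downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .imputation import ImputedCohort


@dataclass(frozen=True)
class CalibrationResult:
    """Calibration of one behaviour's imputation.

    ``excess_matches`` is the derived quantity n·p̂(1−p̂)·ρ̂: the expected
    number of behaviour-present agreements beyond chance. ``valid`` is False
    when the phi coefficient is undefined (a degenerate 2x2 margin).
    """

    n: int
    p_hat: float
    rho_hat: float

    @property
    def excess_matches(self) -> float:
        return self.n * self.p_hat * (1.0 - self.p_hat) * self.rho_hat

    @property
    def valid(self) -> bool:
        return math.isfinite(self.rho_hat)


def prevalence_from_pairs(value_1, value_2) -> float:
    """Prevalence pooled over both imputed vectors: (Σv1 + Σv2) / 2n."""
    v1 = np.asarray(value_1, dtype=float)
    v2 = np.asarray(value_2, dtype=float)
    if v1.size == 0 or v1.size != v2.size:
        raise ValueError("need one or more pairs of equal length")
    return float((v1.sum() + v2.sum()) / (2.0 * v1.size))


def phi_coefficient(value_1, value_2) -> float:
    """Phi coefficient of two binary vectors.

    phi = (n11·n00 − n10·n01) / sqrt(r1·r0·c1·c0) over the 2x2 table of the
    pairs; identical to the Pearson correlation of the 0/1 vectors. Returns
    NaN when any margin is zero (the correlation is then undefined).
    """
    v1 = np.asarray(value_1, dtype=np.int64)
    v2 = np.asarray(value_2, dtype=np.int64)
    if v1.size == 0 or v1.size != v2.size:
        raise ValueError("need one or more pairs of equal length")
    n11 = float(np.sum((v1 == 1) & (v2 == 1)))
    n10 = float(np.sum((v1 == 1) & (v2 == 0)))
    n01 = float(np.sum((v1 == 0) & (v2 == 1)))
    n00 = float(np.sum((v1 == 0) & (v2 == 0)))
    r1, r0 = n11 + n10, n01 + n00
    c1, c0 = n11 + n01, n10 + n00
    denom = r1 * r0 * c1 * c0
    if denom == 0.0:
        return float("nan")
    return (n11 * n00 - n10 * n01) / math.sqrt(denom)


def excess_matches(n: int, p_hat: float, rho_hat: float) -> float:
    """Expected behaviour-present agreements beyond chance: n·p̂(1−p̂)·ρ̂."""
    return n * p_hat * (1.0 - p_hat) * rho_hat


def calibrate_pairs(value_1, value_2) -> CalibrationResult:
    """Calibration statistics from raw paired vectors."""
    v1 = np.asarray(value_1, dtype=np.int64)
    return CalibrationResult(
        n=int(v1.size),
        p_hat=prevalence_from_pairs(value_1, value_2),
        rho_hat=phi_coefficient(value_1, value_2),
    )


def _served_pairs(cohort: ImputedCohort, behaviour: str):
    a = cohort.assignments[behaviour]
    served = a[a["status"] == "served"]
    if len(served) == 0:
        raise ValueError(f"no served recipients for behaviour {behaviour!r}")
    return (
        served["value_1"].to_numpy(dtype=np.int64),
        served["value_2"].to_numpy(dtype=np.int64),
    )


def estimate_prevalence(cohort: ImputedCohort, behaviour: str) -> float:
    """Imputed prevalence of one behaviour, pooled over both imputed values."""
    v1, v2 = _served_pairs(cohort, behaviour)
    return prevalence_from_pairs(v1, v2)


def calibrate(cohort: ImputedCohort, behaviour: str) -> CalibrationResult:
    """Calibration of one behaviour over the cohort's served recipients."""
    v1, v2 = _served_pairs(cohort, behaviour)
    return calibrate_pairs(v1, v2)
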