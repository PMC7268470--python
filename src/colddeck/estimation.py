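"""Relative risks on imputed exposure and the misclassification correction.

Non-differential misclassification of a binary exposure attenuates the risk
ratio toward the null. With calibration parameters p (exposure prevalence)
and ρ (phi correlation between two independent imputations), the observed and
true risk ratios are linked by

    RR_i = 1 + (RR_T − 1)·ρ / [1 + (RR_T − 1)·p·(1 − ρ)]

whose inverse recovers the true risk ratio from the imputed one:

    RR_T = 1 − (RR_i − 1) / [(RR_i − 1)·p·(1 − ρ) − ρ].

The inversion can land below zero when ρ is small relative to sampling noise
in RR_i; such draws are flagged *impossible* rather than raised, and the
repetition engine's failure rule absorbs them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import CalibrationResult


def crude_rr(exposure, death) -> float:
    """Risk ratio from the 2x2 cross-tabulation of exposure vs death.

    Returns NaN (an invalid, not impossible, outcome) when either exposure
    group is empty or there are no deaths among the unexposed.
    """
    e = np.asarray(exposure, dtype=float)
    d = np.asarray(death, dtype=float)
    if e.size != d.size:
        raise ValueError("exposure and death vectors differ in length")
    n1 = float(np.sum(e == 1))
    n0 = float(np.sum(e == 0))
    if n1 == 0 or n0 == 0:
        return float("nan")
    a = float(np.sum((e == 1) & (d == 1)))
    b = float(np.sum((e == 0) & (d == 1)))
    if b == 0:
        return float("nan")
    return (a / n1) / (b / n0)


def cmh_rr(exposure, death, stratum) -> float:
    """Mantel-Haenszel pooled risk ratio across strata (age adjustment).

    MH-RR = Σ_k a_k·n0k/N_k / Σ_k b_k·n1k/N_k, where a/b are exposed and
    unexposed deaths and n1/n0 the group sizes in stratum k. Strata with an
    empty exposure group contribute zero to both sums; a zero denominator
    sum gives NaN (invalid).
    """
    e = np.asarray(exposure, dtype=float)
    d = np.asarray(death, dtype=float)
    s = np.asarray(stratum, dtype=object)
    if not (e.size == d.size == s.size):
        raise ValueError("exposure, death and stratum vectors differ in length")
    num = 0.0
    den = 0.0
    for k in pd.unique(s):
        m = s == k
        ek, dk = e[m], d[m]
        n1 = float(np.sum(ek == 1))
        n0 = float(np.sum(ek == 0))
        if n1 == 0 or n0 == 0:
            continue
        nk = n1 + n0
        a = float(np.sum((ek == 1) & (dk == 1)))
        b = float(np.sum((ek == 0) & (dk == 1)))
        num += a * n0 / nk
        den += b * n1 / nk
    if den == 0.0:
        return float("nan")
    return num / den


def correct_rr(rr_i: float, p: float, rho: float) -> tuple[float, bool]:
    """Invert the attenuation: estimate the true RR from the imputed RR.

    Returns ``(rr_t, impossible)``. The impossible flag is set when the
    corrected value is negative or non-finite, or the denominator is exactly
    zero — the calibration then carries too little information to invert.
    An undefined (NaN) input propagates as invalid, not impossible.
    """
    if not math.isfinite(rr_i) or not math.isfinite(p) or not math.isfinite(rho):
        return float("nan"), False
    denom = (rr_i - 1.0) * p * (1.0 - rho) - rho
    if denom == 0.0:
        return float("nan"), True
    rr_t = 1.0 - (rr_i - 1.0) / denom
    impossible = (rr_t < 0.0) or not math.isfinite(rr_t)
    return rr_t, impossible


def forward_attenuation(rr_t: float, p: float, rho: float) -> float:
    """Imputed-scale RR produced by true RR ``rr_t`` under calibration (p, ρ).

    Exact inverse of :func:`correct_rr`; attenuates toward the null for
    ρ < 1.
    """
    return 1.0 + (rr_t - 1.0) * rho / (1.0 + (rr_t - 1.0) * p * (1.0 - rho))


@dataclass
class EffectEstimate:
    """Crude and age-adjusted relative risks with their corrected versions."""

    rr_i: float
    adj_rr_i: float
    rr_t: float
    adj_rr_t: float
    impossible_crude: bool
    impossible_adjusted: bool


def estimate_effects(
    exposure, death, age_group, calibration: CalibrationResult
) -> EffectEstimate:
    """Full effect estimation for one repetition.

    The same overall calibration (p̂, ρ̂) corrects both the crude and the
    age-adjusted RR, consistent with a model in which behaviour prevalence is
    common across strata.
    """
    rr_i = crude_rr(exposure, death)
    adj_rr_i = cmh_rr(exposure, death, age_group)
    if calibration.valid:
        rr_t, imp_c = correct_rr(rr_i, calibration.p_hat, calibration.rho_hat)
        adj_rr_t, imp_a = correct_rr(adj_rr_i, calibration.p_hat, calibration.rho_hat)
    else:
        rr_t, imp_c = float("nan"), False
        adj_rr_t, imp_a = float("nan"), False
    return EffectEstimate(
        rr_i=rr_i,
        adj_rr_i=adj_rr_i,
        rr_t=rr_t,
        adj_rr_t=adj_rr_t,
        impossible_crude=imp_c,
        impossible_adjusted=imp_a,
    )
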