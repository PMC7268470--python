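"""Synthetic donor pools, recipient cohorts, correlated imputed pairs, and
target-relative-risk survival simulation.

The survival generator is the validation device for the whole pipeline: given
a binary "true" behaviour vector with prevalence p, it draws one-year deaths
with baseline risk R0 = d / (1 + p·(RR − 1)) in the unexposed and R1 = RR·R0
in the exposed, so that the overall death rate stays at d while the risk
ratio between exposure and death is RR by construction. When RR·d exceeds
1 + p·(RR − 1), the required exposed risk is above 1 and the target is
declared not achievable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import AUX_COLUMNS

#: Target relative risks exercised by the validation study.
DEFAULT_TARGET_GRID: tuple[float, ...] = (0.50, 0.66, 0.80, 1.00, 1.25, 1.50, 2.00)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions for one survival simulation.

    target_rr : relative risk of death for exposed vs unexposed.
    death_rate : overall one-year death rate d to be preserved.
    prevalence : nominal exposure prevalence p (used for feasibility checks
        and pair generation; the simulator itself conditions on the empirical
        prevalence of the truth vector it is handed).
    n : cohort size.
    seed : substream seed.
    """

    target_rr: float
    death_rate: float
    prevalence: float
    n: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_rr <= 0:
            raise ValueError("target_rr must be positive")
        if not 0 < self.death_rate < 1:
            raise ValueError("death_rate must be in (0, 1)")
        if not 0 <= self.prevalence <= 1:
            raise ValueError("prevalence must be in [0, 1]")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    def feasible(self) -> bool:
        return not infeasible(self.target_rr, self.death_rate, self.prevalence)


def infeasible(target_rr: float, death_rate: float, prevalence: float) -> bool:
    """True when no pair of per-group risks in [0, 1] realises the target.

    The binding constraint is max(R0, R1) <= 1; for targets above 1 that is
    R1 = target_rr · d / (1 + p·(target_rr − 1)) <= 1.
    """
    r0 = death_rate / (1.0 + prevalence * (target_rr - 1.0))
    return max(r0, target_rr * r0) > 1.0


def generate_correlated_pairs(
    n: int, p: float, rho: float, seed
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n i.i.d. pairs of binary values with common prevalence p and
    phi correlation rho.

    The joint 2x2 law is P11 = p² + p(1−p)ρ, P10 = P01 = p(1−p)(1−ρ),
    P00 = (1−p)² + p(1−p)ρ: chance agreement p² plus an excess-match term
    p(1−p)ρ. Raises ValueError naming the violated cell when the pair
    (p, rho) admits no such joint distribution.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    q = p * (1.0 - p)
    cells = {
        "P11": p * p + q * rho,
        "P10": q * (1.0 - rho),
        "P01": q * (1.0 - rho),
        "P00": (1.0 - p) ** 2 + q * rho,
    }
    eps = 1e-12
    for name, val in cells.items():
        if val < -eps or val > 1.0 + eps:
            raise ValueError(
                f"infeasible (p={p}, rho={rho}): cell {name} = {val:.6g} outside [0, 1]"
            )
    rng = _as_rng(seed)
    c1 = max(cells["P11"], 0.0)
    c2 = c1 + max(cells["P10"], 0.0)
    c3 = c2 + max(cells["P01"], 0.0)
    u = rng.random(n)
    v1 = (u < c2).astype(np.int8)
    v2 = ((u < c1) | ((u >= c2) & (u < c3))).astype(np.int8)
    return v1, v2


def simulate_survival(truth, spec: SimulationSpec, rng=None) -> np.ndarray:
    """Draw one-year death indicators at the spec's target relative risk.

    Risks are conditioned on the *empirical* prevalence of ``truth`` so that
    the realised risk ratio is centred on the target regardless of sampling
    noise in the truth vector. Raises ValueError (message contains
    "not possible") when a required risk exceeds 1.
    """
    truth = np.asarray(truth, dtype=float)
    if truth.size == 0:
        raise ValueError("truth vector is empty")
    p_emp = float(truth.mean())
    r0 = spec.death_rate / (1.0 + p_emp * (spec.target_rr - 1.0))
    r1 = spec.target_rr * r0
    if max(r0, r1) > 1.0 or min(r0, r1) < 0.0:
        raise ValueError(
            f"target RR {spec.target_rr} not possible at prevalence "
            f"{p_emp:.4g} with overall death rate {spec.death_rate}: "
            f"required risks ({r0:.4g}, {r1:.4g}) leave [0, 1]"
        )
    rng = _as_rng(spec.seed if rng is None else rng)
    risk = np.where(truth == 1, r1, r0)
    return (rng.random(truth.size) < risk).astype(np.int8)


def _check_strata(strata: pd.DataFrame) -> list[str]:
    missing = [c for c in (*AUX_COLUMNS, "n") if c not in strata.columns]
    if missing:
        raise ValueError(f"strata spec lacks columns: {missing}")
    if (strata["n"] < 0).any():
        raise ValueError("stratum sizes must be >= 0")
    return [c for c in strata.columns if c not in (*AUX_COLUMNS, "n")]


def generate_donor_pool(
    strata: pd.DataFrame, missing_rate=0.0, seed=0
) -> pd.DataFrame:
    """Generate a survey-like donor table from a per-stratum specification.

    ``strata`` has one row per stratum: the six auxiliary columns, a size
    column ``n``, and one column per behaviour holding that stratum's
    prevalence. ``missing_rate`` (scalar or mapping behaviour -> rate) knocks
    out cells completely at random, independent of the behaviour value.
    """
    behaviours = _check_strata(strata)
    if not behaviours:
        raise ValueError("strata spec declares no behaviour prevalence columns")
    for b in behaviours:
        prev = strata[b].astype(float)
        if ((prev < 0) | (prev > 1)).any():
            raise ValueError(f"prevalences for {b!r} must lie in [0, 1]")
    if not isinstance(missing_rate, dict):
        missing_rate = {b: float(missing_rate) for b in behaviours}
    rng = _as_rng(seed)

    sizes = strata["n"].astype(int).to_numpy()
    expanded = strata.loc[strata.index.repeat(sizes), list(AUX_COLUMNS)].reset_index(
        drop=True
    )
    total = len(expanded)
    out = pd.DataFrame({"id": [f"D{i:07d}" for i in range(total)]})
    for col in AUX_COLUMNS:
        out[col] = expanded[col].to_numpy()
    out["year"] = out["year"].astype("Int64")
    for b in behaviours:
        prev = np.repeat(strata[b].astype(float).to_numpy(), sizes)
        vals = pd.array((rng.random(total) < prev).astype(int), dtype="Int64")
        rate = missing_rate.get(b, 0.0)
        if rate > 0:
            vals[rng.random(total) < rate] = pd.NA
        out[b] = vals
    return out


def generate_recipient_cohort(
    strata: pd.DataFrame, seed=0, death_rate: float | None = None
) -> pd.DataFrame:
    """Generate a registry-like recipient cohort with exact per-stratum counts.

    The outcome column is left missing unless ``death_rate`` is given, in
    which case deaths are drawn Bernoulli(death_rate) independent of stratum.
    """
    extra = _check_strata(strata)
    rng = _as_rng(seed)
    sizes = strata["n"].astype(int).to_numpy()
    expanded = strata.loc[strata.index.repeat(sizes), list(AUX_COLUMNS)].reset_index(
        drop=True
    )
    total = len(expanded)
    out = pd.DataFrame({"id": [f"R{i:07d}" for i in range(total)]})
    for col in AUX_COLUMNS:
        out[col] = expanded[col].to_numpy()
    out["year"] = out["year"].astype("Int64")
    if death_rate is None:
        out["death_within_1yr"] = pd.array([pd.NA] * total, dtype="Int64")
    else:
        out["death_within_1yr"] = pd.array(
            (rng.random(total) < float(death_rate)).astype(int), dtype="Int64"
        )
    if "subgroup" in extra:
        out["subgroup"] = np.repeat(strata["subgroup"].to_numpy(), sizes)
    return out
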