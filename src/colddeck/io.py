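"""Reading and writing the package's delimited-text artifacts.

Interchange format is UTF-8 CSV with a header row. Missing values are empty
strings on disk and ``pandas.NA`` in memory (behaviour, outcome and year
columns use nullable integer dtypes).
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import (
    AUX_COLUMNS,
    CORRECTED_ESTIMANDS,
    DONOR_REQUIRED,
    RECIPIENT_REQUIRED,
    SENTINEL_FAILED,
    SENTINEL_NOT_POSSIBLE,
    SUBGROUP_COLUMN,
    RepetitionSummary,
    StudyConfig,
)

logger = logging.getLogger("colddeck")

_RESULT_COLUMNS = (
    "behaviour",
    "subgroup",
    "target_rr",
    "estimand",
    "n",
    "median",
    "lower",
    "upper",
    "impossible_count",
    "invalid_count",
    "failed",
)


def _to_binary(series: pd.Series, column: str) -> pd.Series:
    """Coerce a column of strings to nullable {0,1}; log coercion failures."""
    num = pd.to_numeric(series.replace("", pd.NA), errors="coerce")
    bad = num.notna() & ~num.isin([0, 1])
    unparseable = series.notna() & (series != "") & num.isna()
    n_bad = int(bad.sum() + unparseable.sum())
    if n_bad:
        logger.warning("%s: %d unparseable values set to missing", column, n_bad)
    num[bad] = pd.NA
    return num.astype("Int64")


def read_table(path, role: str, config: StudyConfig | None = None) -> pd.DataFrame:
    """Read a donor or recipient CSV into a typed DataFrame.

    Parameters
    ----------
    path
        CSV file with a header row; header matching is case-insensitive.
    role
        ``"recipient"`` or ``"donor"``; selects the mandatory column set.
    config
        Optional study configuration; when given, declared behaviour columns
        are required in donor tables and declared category lists are enforced
        (out-of-list cells become missing, with a logged count).
    """
    if role not in ("recipient", "donor"):
        raise ValueError(f"unknown table role: {role!r}")
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    df.columns = [c.strip().lower() for c in df.columns]
    if len(df) == 0:
        raise ValueError(f"{path}: file contains no records")

    required = RECIPIENT_REQUIRED if role == "recipient" else DONOR_REQUIRED
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")

    behaviours: Sequence[str]
    if role == "donor":
        behaviours = [c for c in df.columns if c not in DONOR_REQUIRED]
        if config is not None:
            for b in config.behaviours:
                if b not in df.columns:
                    raise ValueError(f"{path}: missing behaviour column {b!r}")
            behaviours = list(config.behaviours)
        if not behaviours:
            raise ValueError(f"{path}: donor table declares no behaviour columns")
    else:
        behaviours = []

    out = pd.DataFrame(index=df.index)
    out["id"] = df["id"].str.strip()
    if out["id"].duplicated().any():
        dup = out["id"][out["id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate id {dup!r}")

    for col in AUX_COLUMNS:
        if col == "year":
            out[col] = pd.to_numeric(df[col].replace("", pd.NA), errors="coerce").astype(
                "Int64"
            )
            continue
        vals = df[col].str.strip().replace("", pd.NA)
        allowed = None
        if config is not None:
            if col == "age_group":
                allowed = config.age_groups
            elif config.categories and col in config.categories:
                allowed = config.categories[col]
        if allowed is not None:
            bad = vals.notna() & ~vals.isin(allowed)
            if bad.any():
                logger.warning(
                    "%s: %d values outside declared categories set to missing",
                    col,
                    int(bad.sum()),
                )
                vals = vals.mask(bad)
        out[col] = vals

    if role == "recipient":
        out["death_within_1yr"] = _to_binary(df["death_within_1yr"], "death_within_1yr")
        if SUBGROUP_COLUMN in df.columns:
            out[SUBGROUP_COLUMN] = df[SUBGROUP_COLUMN].str.strip().replace("", pd.NA)
    else:
        for b in behaviours:
            out[b] = _to_binary(df[b], b)
    return out


def exclude_incomplete(
    table: pd.DataFrame, role: str = "recipient"
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop rows with missing auxiliary values (and outcome, for recipients).

    Returns the retained table and an accounting dict whose entries sum to
    the input row count (``kept + excluded_missing == n_input``).
    """
    cols = list(AUX_COLUMNS)
    if role == "recipient":
        cols.append("death_within_1yr")
    complete = table[cols].notna().all(axis=1)
    counts = {
        "n_input": len(table),
        "kept": int(complete.sum()),
        "excluded_missing": int((~complete).sum()),
    }
    if counts["excluded_missing"]:
        logger.info(
            "%s table: excluded %d of %d rows with missing values",
            role,
            counts["excluded_missing"],
            counts["n_input"],
        )
    return table[complete].copy(), counts


def results_frame(summaries: Iterable[RepetitionSummary]) -> pd.DataFrame:
    """Render repetition summaries as the delimited results table.

    Corrected-RR rows of failed behaviours carry the ``failed`` sentinel in
    their median/interval cells; infeasible simulation targets carry
    ``Not possible``.
    """
    rows = []
    for s in summaries:
        row = {
            "behaviour": s.behaviour,
            "subgroup": s.subgroup,
            "target_rr": s.target_rr,
            "estimand": s.estimand,
            "n": s.n,
            "median": s.median,
            "lower": s.lower,
            "upper": s.upper,
            "impossible_count": s.impossible_count,
            "invalid_count": s.invalid_count,
            "failed": s.failed,
        }
        if s.not_possible:
            row["median"] = row["lower"] = row["upper"] = SENTINEL_NOT_POSSIBLE
        elif s.failed and s.estimand in CORRECTED_ESTIMANDS:
            row["median"] = row["lower"] = row["upper"] = SENTINEL_FAILED
        rows.append(row)
    return pd.DataFrame(rows, columns=_RESULT_COLUMNS)


def write_results(
    summaries: Iterable[RepetitionSummary],
    path,
    draws: pd.DataFrame | None = None,
    draws_path=None,
) -> None:
    """Write the results table, and optionally the per-repetition sidecar."""
    results_frame(summaries).to_csv(path, index=False)
    if draws is not None:
        if draws_path is None:
            raise ValueError("draws_path required when draws are given")
        draws.to_csv(draws_path, index=False)


def read_results(path) -> pd.DataFrame:
    """Read a results table back; sentinel cells stay as strings."""
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    for col in ("target_rr", "n", "median", "lower", "upper"):
        parsed = pd.to_numeric(df[col].replace("", pd.NA), errors="coerce")
        sentinel = df[col].isin([SENTINEL_FAILED, SENTINEL_NOT_POSSIBLE])
        df[col] = df[col].where(sentinel, parsed)
    for col in ("impossible_count", "invalid_count"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    df["failed"] = df["failed"].map({"True": True, "False": False})
    return df
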