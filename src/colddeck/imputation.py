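"""Stratified random cold-deck imputation.

Each recipient (registry case) is matched to the donor stratum with the same
gender, marital status, race and region, a survey year ``lag_years`` before
the diagnosis year, and an age band ``age_group_shift`` bands younger (the
donor reports behaviour as it was before the recipient's diagnosis). Within
each stratum, donors are assigned uniformly at random *without replacement*:
every recipient consumes two distinct donors, so two imputed values per
behaviour are available for calibration. When a stratum runs out of donor
pairs the remaining recipients are excluded and counted; recipients whose
shifted stratum holds no donors at all (including those already in the
youngest age band) are excluded separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    AUX_COLUMNS,
    STATUS_EXHAUSTED,
    STATUS_NO_STRATUM,
    STATUS_SERVED,
    StudyConfig,
)
from .synthetic import _as_rng

_KEY_COLUMNS = list(AUX_COLUMNS)


def build_donor_datasets(
    donors: pd.DataFrame, behaviours
) -> dict[str, pd.DataFrame]:
    """One complete-case donor dataset per behaviour.

    Dropping donors missing a given behaviour (rather than all donors with
    any missing behaviour) keeps each behaviour's pool as large as possible
    and avoids imputing a missing value into a missing value.
    """
    datasets: dict[str, pd.DataFrame] = {}
    for b in behaviours:
        if b not in donors.columns:
            raise ValueError(f"donor table lacks behaviour column {b!r}")
        ds = donors[donors[b].notna()]
        if len(ds) == 0:
            raise ValueError(f"behaviour {b!r} has no non-missing donor records")
        datasets[b] = ds.reset_index(drop=True)
    return datasets


def impute_double(
    recipients: pd.DataFrame,
    donor_dataset: pd.DataFrame,
    behaviour: str,
    config: StudyConfig,
    seed,
) -> pd.DataFrame:
    """Assign two distinct random donors from the lag-shifted stratum to each
    recipient.

    Returns a frame aligned with ``recipients``: columns ``id``, ``value_1``,
    ``value_2``, ``donor_1``, ``donor_2``, ``status``. Recipients are
    processed in a random permutation within each stratum so that
    exhaustion-based exclusion does not depend on input order.
    """
    rng = _as_rng(seed)
    n = len(recipients)
    value_1 = np.full(n, -1, dtype=np.int64)
    value_2 = np.full(n, -1, dtype=np.int64)
    donor_1 = np.full(n, "", dtype=object)
    donor_2 = np.full(n, "", dtype=object)
    status = np.full(n, STATUS_NO_STRATUM, dtype=object)

    age_index = {g: i for i, g in enumerate(config.age_groups)}
    ridx = recipients["age_group"].map(age_index)
    shifted = ridx - config.age_group_shift
    matchable = (ridx.notna() & (shifted >= 0)).fillna(False).astype(bool)

    key = pd.DataFrame(index=recipients.index)
    groups_list = list(config.age_groups)
    key["age_group"] = shifted.where(matchable).map(
        lambda i: groups_list[int(i)] if pd.notna(i) else None
    )
    for col in ("gender", "marital_status", "race", "region"):
        key[col] = recipients[col].astype(object)
    key["year"] = (recipients["year"].astype("Int64") - config.lag_years).astype(object)

    dkey = donor_dataset[_KEY_COLUMNS].copy()
    for col in ("age_group", "gender", "marital_status", "race", "region"):
        dkey[col] = dkey[col].astype(object)
    dkey["year"] = dkey["year"].astype("Int64").astype(object)
    donor_groups = dkey.groupby(_KEY_COLUMNS, sort=False, dropna=True).indices
    donor_vals = donor_dataset[behaviour].to_numpy(dtype=np.int64)
    donor_ids = donor_dataset["id"].to_numpy(dtype=object)

    pos = np.arange(n)
    rec_groups = key[matchable.to_numpy()].groupby(_KEY_COLUMNS, sort=False).indices
    matchable_pos = pos[matchable.to_numpy()]
    for k, rel in rec_groups.items():
        rpos = matchable_pos[rel]
        dpos = donor_groups.get(k)
        if dpos is None:
            continue  # stays no_donor_stratum
        rperm = rng.permutation(rpos)
        dperm = rng.permutation(dpos)
        n_served = min(len(rperm), len(dperm) // 2)
        served = rperm[:n_served]
        first = dperm[0 : 2 * n_served : 2]
        second = dperm[1 : 2 * n_served : 2]
        value_1[served] = donor_vals[first]
        value_2[served] = donor_vals[second]
        donor_1[served] = donor_ids[first]
        donor_2[served] = donor_ids[second]
        status[served] = STATUS_SERVED
        status[rperm[n_served:]] = STATUS_EXHAUSTED

    out = pd.DataFrame(
        {
            "id": recipients["id"].to_numpy(),
            "behaviour": behaviour,
            "value_1": pd.array(
                [v if v >= 0 else pd.NA for v in value_1], dtype="Int64"
            ),
            "value_2": pd.array(
                [v if v >= 0 else pd.NA for v in value_2], dtype="Int64"
            ),
            "donor_1": [d if d else pd.NA for d in donor_1],
            "donor_2": [d if d else pd.NA for d in donor_2],
            "status": status,
        }
    )
    return out


@dataclass
class ImputedCohort:
    """Recipients annotated with two imputed values per behaviour."""

    recipients: pd.DataFrame
    assignments: dict[str, pd.DataFrame] = field(default_factory=dict)

    def served(self, behaviour: str) -> pd.DataFrame:
        """Served assignments for one behaviour, joined with recipient fields."""
        a = self.assignments[behaviour]
        served = a[a["status"] == STATUS_SERVED]
        return served.merge(self.recipients, on="id", how="left")

    def to_frame(self) -> pd.DataFrame:
        """Long-format serialisation: id, behaviour, value_1, value_2, status."""
        if not self.assignments:
            return pd.DataFrame(
                columns=["id", "behaviour", "value_1", "value_2", "status"]
            )
        return pd.concat(self.assignments.values(), ignore_index=True)


def impute_cohort(
    recipients: pd.DataFrame,
    donors: pd.DataFrame,
    config: StudyConfig,
    seed,
) -> ImputedCohort:
    """Run double imputation for every configured behaviour."""
    rng = _as_rng(seed)
    datasets = build_donor_datasets(donors, config.behaviours)
    cohort = ImputedCohort(recipients=recipients)
    for b in config.behaviours:
        cohort.assignments[b] = impute_double(recipients, datasets[b], b, config, rng)
    return cohort


def imputation_report(cohort: ImputedCohort) -> pd.DataFrame:
    """Per-behaviour exclusion accounting; counts sum to the input row count."""
    rows = []
    n_input = len(cohort.recipients)
    for b, a in cohort.assignments.items():
        counts = a["status"].value_counts()
        served = int(counts.get(STATUS_SERVED, 0))
        exhausted = int(counts.get(STATUS_EXHAUSTED, 0))
        no_stratum = int(counts.get(STATUS_NO_STRATUM, 0))
        rows.append(
            {
                "behaviour": b,
                "n_input": n_input,
                "served": served,
                "excluded_exhausted": exhausted,
                "excluded_no_stratum": no_stratum,
            }
        )
    return pd.DataFrame(rows)
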