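"""Proportion of days covered (PDC) over a fixed 180-day window.

For each adherence-eligible index claim, the PDC is the fraction of the
180 days starting at the index fill date (the fill day itself is covered
day 1) on which the patient had any medication of the index class
available, based on days supplied.  Overlapping supplies are by default
shifted forward ("stockpiling"): a fill dispensed while a prior supply is
still active starts contributing the day after that supply runs out.  A
``truncate`` mode discards the overlap instead.  Supply running past the
window end is not counted.

Any medication within the index class counts — switching tier or product
mid-window does not break coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

WINDOW_DAYS = 180


@dataclass(frozen=True)
class PdcRecord:
    """PDC of one index claim over its 180-day window."""

    claim_id: str | None
    covered_days: int
    pdc: float
    window_start: pd.Timestamp
    window_end: pd.Timestamp  # exclusive
    right_censored: bool = False


def compute_pdc(
    index_claim,
    same_class_claims: pd.DataFrame,
    overlap: str = "shift",
    window_days: int = WINDOW_DAYS,
    data_end: date | None = None,
) -> PdcRecord:
    """PDC for a single index claim.

    ``same_class_claims`` must contain *all* of the patient's claims of the
    index class (any tier or product), including the index claim itself.
    ``overlap='shift'`` queues overlapping supply forward; ``'truncate'``
    counts each fill only on its own dispensed days.  If the window runs
    past ``data_end`` the record is computed anyway and flagged
    right-censored.
    """
    if overlap not in ("shift", "truncate"):
        raise ValueError("overlap must be 'shift' or 'truncate'")
    start = pd.Timestamp(index_claim["fill_date"])
    window_end = start + pd.Timedelta(days=window_days)
    fills = same_class_claims[["fill_date", "days_supplied"]].copy()
    fills["fill_date"] = pd.to_datetime(fills["fill_date"])
    fills = fills.sort_values("fill_date", kind="mergesort")

    covered = 0
    if overlap == "shift":
        supply_end = None  # exclusive end of the current contiguous supply
        for fill, days in zip(fills["fill_date"], fills["days_supplied"]):
            if fill >= window_end:
                break
            s = fill if supply_end is None or fill > supply_end else supply_end
            e = s + pd.Timedelta(days=int(days))
            supply_end = e
            lo = max(s, start)
            hi = min(e, window_end)
            if hi > lo:
                covered += (hi - lo).days
    else:
        day0 = np.zeros(window_days, dtype=bool)
        for fill, days in zip(fills["fill_date"], fills["days_supplied"]):
            a = (fill - start).days
            b = a + int(days)
            a, b = max(a, 0), min(b, window_days)
            if b > a:
                day0[a:b] = True
        covered = int(day0.sum())

    censored = data_end is not None and window_end > pd.Timestamp(data_end)
    return PdcRecord(
        claim_id=index_claim.get("claim_id") if hasattr(index_claim, "get") else None,
        covered_days=int(covered),
        pdc=covered / window_days,
        window_start=start,
        window_end=window_end,
        right_censored=bool(censored),
    )


def compute_pdc_table(
    cohort: pd.DataFrame,
    claims: pd.DataFrame,
    overlap: str = "shift",
    window_days: int = WINDOW_DAYS,
    data_end: date | None = None,
    eligible_only: bool = True,
) -> pd.DataFrame:
    """PDC for every (eligible) index claim of a cohort.

    Joins each index claim against the patient's same-class claims and
    returns the cohort rows augmented with ``covered_days``, ``pdc`` and a
    right-censoring flag.
    """
    rows = cohort
    if eligible_only and "eligible_for_adherence" in cohort:
        rows = cohort[cohort["eligible_for_adherence"]]
    claims = claims.copy()
    claims["fill_date"] = pd.to_datetime(claims["fill_date"])
    grouped = {
        key: df for key, df in claims.groupby(["patient_id", "med_class"], sort=False)
    }
    out = rows.copy()
    covered = np.empty(len(rows), dtype=int)
    censored = np.empty(len(rows), dtype=bool)
    for i, (_, claim) in enumerate(rows.iterrows()):
        fills = grouped.get((claim["patient_id"], claim["med_class"]))
        if fills is None:  # index claim must at least cover itself
            raise KeyError(
                f"no claims found for patient {claim['patient_id']} "
                f"class {claim['med_class']}"
            )
        rec = compute_pdc(
            claim, fills, overlap=overlap, window_days=window_days, data_end=data_end
        )
        covered[i] = rec.covered_days
        censored[i] = rec.right_censored
    out["covered_days"] = covered
    out["pdc"] = covered / window_days
    out["right_censored"] = censored
    return out
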