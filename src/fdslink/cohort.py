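"""New-user cohort construction from a raw claims table.

The exclusion cascade mirrors a standard new-user pharmacy-claims design:

1. drop claims with fewer than 15 days supplied (trial starts and
   apparently erroneous records);
2. keep only "index" claims — claims not preceded by another same-class
   claim in the prior 180 days (the new-user washout);
3. flag index claims from 2006 as ineligible for the adherence analysis
   (they lack a full 180-day follow-up in the extract); they remain in the
   tier analyses.

Every prescriber must carry exactly one *effective* activation date:
adopters their real date, non-adopters a synthetic date sampled with
replacement from adopters' real dates so that control claims can be split
into the same three exposure periods (pre-FDS, non-interruptive FDS only,
both interruptive and non-interruptive FDS).
"""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd

PERIOD_PRE = "pre"
PERIOD_NONINTERRUPTIVE = "noninterruptive_only"
PERIOD_BOTH = "both_fds"

USAGE_THRESHOLD = 0.30  # high user iff usage_rate >= 0.30 (ties upward)


def filter_min_days(claims: pd.DataFrame, min_days: int = 15) -> pd.DataFrame:
    """Drop claims with fewer than ``min_days`` days supplied.

    Input row order is preserved; the boundary (exactly 15 days) is kept.
    """
    return claims[claims["days_supplied"] >= min_days].copy()


def identify_index_claims(
    claims: pd.DataFrame, washout_days: int = 180
) -> pd.DataFrame:
    """Keep claims with no same-class claim in the prior washout window.

    A claim dated ``d`` is an index claim iff the same patient has no claim
    of the same medication class with fill date in ``[d - washout_days, d)``.
    Claims of the other class never block; same-day duplicates do not block
    each other (the window excludes ``d`` itself).  The retained set is
    independent of the input row order.
    """
    if claims.empty:
        return claims.copy()
    work = claims[["patient_id", "med_class", "fill_date"]].copy()
    work["fill_date"] = pd.to_datetime(work["fill_date"])
    # Gap to the previous *distinct* fill date within patient x class.
    uniq = (
        work.drop_duplicates()
        .sort_values(["patient_id", "med_class", "fill_date"], kind="mergesort")
        .reset_index(drop=True)
    )
    gap = uniq.groupby(["patient_id", "med_class"], sort=False)["fill_date"].diff()
    uniq["is_index"] = gap.isna() | (gap > pd.Timedelta(days=washout_days))
    flagged = work.reset_index().merge(
        uniq, on=["patient_id", "med_class", "fill_date"], how="left"
    )
    keep = flagged.set_index("index")["is_index"]
    return claims[keep.reindex(claims.index).to_numpy()].copy()


def flag_adherence_eligibility(
    index_claims: pd.DataFrame, cutoff: date = date(2006, 1, 1)
) -> pd.DataFrame:
    """Mark index claims with a full 180-day follow-up in the extract.

    Claims filled on or after ``cutoff`` (calendar 2006 by default) are
    retained but flagged ineligible for the adherence analysis; no rows are
    dropped because the tier analyses use all index claims.
    """
    out = index_claims.copy()
    out["eligible_for_adherence"] = pd.to_datetime(out["fill_date"]) < pd.Timestamp(
        cutoff
    )
    return out


def assign_synthetic_dates(
    pcps: pd.DataFrame, rng: np.random.Generator, overwrite: bool = False
) -> pd.DataFrame:
    """Give every non-adopter a synthetic activation date.

    Dates are sampled i.i.d. with replacement from the multiset of
    adopters' real activation dates, making the activation-date
    distribution comparable between adopters and controls.  Prescribers
    that already carry a synthetic date are left alone unless
    ``overwrite=True`` (a generator may have pre-assigned dates that were
    used to draw exposure-dependent outcomes).
    """
    out = pcps.copy()
    adopter_dates = pd.to_datetime(out["activation_date"]).dropna()
    needs = out["activation_date"].isna()
    if not overwrite:
        needs &= out["synthetic_activation_date"].isna()
    if needs.any():
        if adopter_dates.empty:
            raise ValueError(
                "no adopters with a real activation date: the empirical "
                "distribution for synthetic dates is undefined"
            )
        draws = rng.choice(adopter_dates.to_numpy(), size=int(needs.sum()), replace=True)
        out.loc[needs, "synthetic_activation_date"] = draws
    out["synthetic_activation_date"] = pd.to_datetime(out["synthetic_activation_date"])
    return out


def effective_activation_dates(pcps: pd.DataFrame) -> pd.Series:
    """Real activation date where present, synthetic otherwise."""
    eff = pd.to_datetime(pcps["activation_date"]).fillna(
        pd.to_datetime(pcps["synthetic_activation_date"])
    )
    if eff.isna().any():
        missing = pcps.loc[eff.isna(), "pcp_id"].tolist()[:5]
        raise ValueError(f"prescribers lacking an effective activation date: {missing}")
    return pd.Series(eff.to_numpy(), index=pcps["pcp_id"].to_numpy(), name="effective_activation")


def classify_period(fill_date, effective_activation, interruptive_start) -> str:
    """Exposure period of one claim.

    ``pre`` before the effective activation date; ``noninterruptive_only``
    from activation (inclusive) until the interruptive go-live;
    ``both_fds`` from ``max(activation, interruptive_start)`` (inclusive).
    The three labels partition all dates; boundary days count as exposed
    because activation enables e-prescribing the same day.
    """
    fill = pd.Timestamp(fill_date)
    act = pd.Timestamp(effective_activation)
    go_live = pd.Timestamp(interruptive_start)
    if fill < act:
        return PERIOD_PRE
    if fill < go_live:
        return PERIOD_NONINTERRUPTIVE
    return PERIOD_BOTH


def label_periods(
    claims: pd.DataFrame, pcps: pd.DataFrame, interruptive_start: date
) -> pd.DataFrame:
    """Vectorized period labels for a claims table."""
    eff = effective_activation_dates(pcps)
    act = claims["pcp_id"].map(eff)
    if act.isna().any():
        missing = claims.loc[act.isna(), "pcp_id"].unique().tolist()[:5]
        raise ValueError(f"claims reference unknown prescribers: {missing}")
    fill = pd.to_datetime(claims["fill_date"])
    go_live = pd.Timestamp(interruptive_start)
    out = claims.copy()
    period = np.full(len(out), PERIOD_PRE, dtype=object)
    post = (fill >= act.to_numpy()).to_numpy()
    period[post & (fill < go_live).to_numpy()] = PERIOD_NONINTERRUPTIVE
    period[post & (fill >= go_live).to_numpy()] = PERIOD_BOTH
    out["period"] = period
    return out


def monthly_copayment(claims: pd.DataFrame) -> pd.Series:
    """Copayment standardized to dollars per 30-day month.

    ``copayment x 30 / days_supplied``; raises on non-positive supplies.
    """
    days = claims["days_supplied"]
    if (days <= 0).any():
        raise ValueError("days_supplied must be positive to normalize copayment")
    return claims["copayment_dollars"] * 30.0 / days


def usage_group(usage_rate: float, adopter: bool) -> str:
    """non / low / high usage classification (high iff rate >= 0.30)."""
    if not adopter or usage_rate == 0:
        return "non"
    return "high" if usage_rate >= USAGE_THRESHOLD else "low"


def build_cohort(
    claims: pd.DataFrame,
    pcps: pd.DataFrame,
    rng: np.random.Generator | None = None,
    interruptive_start: date = date(2005, 9, 16),
    min_days: int = 15,
    washout_days: int = 180,
    adherence_cutoff: date = date(2006, 1, 1),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Run the full exclusion cascade and label index claims.

    Order matters and is fixed: the minimum-days filter runs first, so
    sub-15-day claims also cannot block a later claim from being index;
    then index identification, then the adherence-eligibility flag.
    Returns the labeled index-claim table and the exclusion counts of each
    step.
    """
    counts = {"raw_claims": int(len(claims))}
    step = filter_min_days(claims, min_days=min_days)
    counts["after_min_days"] = int(len(step))
    step = identify_index_claims(step, washout_days=washout_days)
    counts["index_claims"] = int(len(step))
    step = flag_adherence_eligibility(step, cutoff=adherence_cutoff)
    counts["adherence_eligible"] = int(step["eligible_for_adherence"].sum())

    pcps_eff = pcps
    if pcps["activation_date"].isna().any():
        need_synth = (
            pcps["activation_date"].isna() & pcps["synthetic_activation_date"].isna()
        )
        if need_synth.any():
            if rng is None:
                raise ValueError(
                    "rng required: non-adopters lack synthetic activation dates"
                )
            pcps_eff = assign_synthetic_dates(pcps, rng)
    cohort = label_periods(step, pcps_eff, interruptive_start)
    carry = ["pcp_id", "group"] + (
        ["specialty"] if "specialty" in pcps_eff.columns else []
    )
    cohort = cohort.merge(pcps_eff[carry], on="pcp_id", how="left")
    cohort["monthly_copayment"] = monthly_copayment(cohort)
    return cohort.reset_index(drop=True), counts
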