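"""Seeded synthetic pharmacy-claims generator.

Emulates the statistical structure of a three-year pharmacy-claims extract
for two brand-only medication classes dispensed to primary-care patients of
prescribers who were offered e-prescribing with formulary decision support
(FDS):

* prescriber roster with usage group (non / low / high user), a usage rate
  consistent with the group, and a 2005 activation date (real for adopters,
  synthetic for non-adopters, both drawn from the same empirical
  distribution so control prescribers can be split into the same exposure
  periods);
* patient roster with age, sex and neighborhood-income stratum;
* a claims stream: one new-use ("index") dispensing per patient episode,
  with medication tier drawn from the configured group x period x class
  preferred-tier probability, a monthly copayment drawn from the class x
  tier copayment model, and 30-day refill claims spaced so that the
  realized 180-day proportion of days covered (PDC) matches a target drawn
  from the configured linear adherence model.

Partial adherence is realized by gaps between 30-day refills (the final
refill may straddle the 180-day window so any integer number of covered
days is representable); supplies are never shortened.
"""

from __future__ import annotations

import warnings
from datetime import timedelta

import numpy as np
import pandas as pd

from .config import CLASSES, GROUPS, INCOME_STRATA, PERIODS, SimulationConfig

PDC_WINDOW_DAYS = 180
FILL_DAYS = 30

#: Specialty mix per usage group (family practice, internal medicine,
#: non-surgical other, pediatrics), roster marginals.
SPECIALTIES = ("family_practice", "internal_medicine", "non_surgical", "pediatrics")
SPECIALTY_MIX = {
    "non": (0.31, 0.54, 0.0013, 0.15),
    "low": (0.36, 0.55, 0.0053, 0.086),
    "high": (0.38, 0.47, 0.014, 0.14),
}

#: Practice-size category mix per usage group.
PRACTICE_SIZES = ("1", "2-5", "6-10", "11-25", ">25")
PRACTICE_SIZE_MIX = {
    "non": (0.50, 0.39, 0.10, 0.013, 0.0013),
    "low": (0.34, 0.48, 0.16, 0.016, 0.0),
    "high": (0.39, 0.53, 0.081, 0.0, 0.0),
}


def _normalized(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    return p / p.sum()


def _bounded_pdc_noise(
    mean: np.ndarray, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Mean plus residual noise, bounded to [0, 1] without biasing the mean.

    The residual is Gaussian truncated *symmetrically* to
    ``+-min(mean, 1 - mean)``, so the draw stays in [0, 1] while the
    conditional expectation remains exactly the (clipped) linear mean —
    one-sided clipping would attenuate the very regression coefficients
    the generator is meant to embody.
    """
    from scipy.stats import truncnorm

    m = np.clip(np.asarray(mean, dtype=float), 0.0, 1.0)
    if sd == 0:
        return m
    c = np.minimum(m, 1.0 - m)
    out = m.copy()
    ok = c > 1e-12
    if ok.any():
        lim = c[ok] / sd
        out[ok] = m[ok] + truncnorm.rvs(
            -lim, lim, scale=sd, size=int(ok.sum()), random_state=rng
        )
    return out


def _as_timestamp(d) -> pd.Timestamp:
    return pd.Timestamp(d)


def generate_rosters(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the prescriber and patient rosters.

    Returns ``(pcps, patients)``.  Non-users have usage rate 0 and a
    synthetic activation date; low users draw a rate below 0.30; high users
    draw 0.30 + 0.70 x Beta(a, b) (mean 0.61 by default).  Each patient
    belongs to exactly one prescriber.
    """
    config.validate()
    act_pool = np.array(
        [_as_timestamp(d) for d in config.activation_dates], dtype="datetime64[ns]"
    )

    rows = []
    counter = 0
    for group in GROUPS:
        n = config.n_pcps_per_group.get(group, 0)
        if group == "non":
            usage = np.zeros(n)
        elif group == "low":
            lo, hi = config.low_usage_range
            usage = rng.uniform(lo, hi, size=n)
        else:
            a, b = config.high_usage_beta
            usage = 0.30 + 0.70 * rng.beta(a, b, size=n)
        activation = rng.choice(act_pool, size=n, replace=True)
        specialty = rng.choice(
            np.array(SPECIALTIES, dtype=object),
            size=n,
            p=_normalized(SPECIALTY_MIX[group]),
        )
        practice = rng.choice(
            np.array(PRACTICE_SIZES, dtype=object),
            size=n,
            p=_normalized(PRACTICE_SIZE_MIX[group]),
        )
        for i in range(n):
            counter += 1
            rows.append(
                {
                    "pcp_id": f"P{counter:05d}",
                    "group": group,
                    "usage_rate": float(usage[i]),
                    "specialty": specialty[i],
                    "practice_size": practice[i],
                    "activation_date": pd.NaT if group == "non" else activation[i],
                    "synthetic_activation_date": (
                        activation[i] if group == "non" else pd.NaT
                    ),
                }
            )
    pcps = pd.DataFrame(rows)
    for col in ("activation_date", "synthetic_activation_date"):
        pcps[col] = pd.to_datetime(pcps[col])

    n_patients = len(pcps) * config.patients_per_pcp
    income = rng.choice(
        np.array(INCOME_STRATA, dtype=object),
        size=n_patients,
        p=[config.income_mix[s] for s in INCOME_STRATA],
    )
    age = np.clip(rng.normal(config.age_mean, config.age_sd, size=n_patients), 2, 95)
    sex = np.where(rng.random(n_patients) < config.p_female, "F", "M")
    patients = pd.DataFrame(
        {
            "patient_id": [f"PT{i + 1:07d}" for i in range(n_patients)],
            "pcp_id": np.repeat(pcps["pcp_id"].to_numpy(), config.patients_per_pcp),
            "age": np.round(age, 1),
            "sex": sex,
            "income": income,
        }
    )
    return pcps, patients


def _effective_activation(pcps: pd.DataFrame) -> pd.Series:
    eff = pcps["activation_date"].fillna(pcps["synthetic_activation_date"])
    if eff.isna().any():
        missing = pcps.loc[eff.isna(), "pcp_id"].tolist()[:5]
        raise ValueError(f"prescribers without any activation date: {missing}")
    return eff


def _period_labels(
    fill_date: np.ndarray, activation: np.ndarray, interruptive: np.datetime64
) -> np.ndarray:
    """Exposure period per claim; boundary days count as exposed."""
    labels = np.full(fill_date.shape, "pre", dtype=object)
    post = fill_date >= activation
    labels[post & (fill_date < interruptive)] = "noninterruptive_only"
    labels[post & (fill_date >= interruptive)] = "both_fds"
    return labels


def fills_for_covered_days(covered: int) -> list[int]:
    """Fill-day offsets realizing exactly ``covered`` days within the window.

    Full 30-day supplies are placed back-to-back from day 0; a remainder is
    realized by one final 30-day fill placed so that only ``covered % 30``
    of its days fall inside the 180-day window.
    """
    if not 0 <= covered <= PDC_WINDOW_DAYS:
        raise ValueError("covered days must lie in [0, 180]")
    n_full, rem = divmod(covered, FILL_DAYS)
    offsets = [j * FILL_DAYS for j in range(n_full)]
    if rem:
        offsets.append(PDC_WINDOW_DAYS - rem)
    return offsets


def generate_claims(
    config: SimulationConfig,
    pcps: pd.DataFrame,
    patients: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw the claims stream for the rostered patients.

    One new-start episode per patient per ``episodes_per_patient``; the
    index fill date is uniform over the study window, tier and copayment
    are drawn from the configured cell models given the prescriber's
    exposure period, and refills realize the targeted 180-day PDC exactly
    at day resolution (floored at one fill, i.e. PDC >= 30/180).
    Refills dated after the study window end are dropped, mirroring a
    fixed extract date.
    """
    config.validate()
    eff = _effective_activation(pcps)
    pcp_info = pcps[["pcp_id", "group"]].copy()
    pcp_info["effective_activation"] = eff.to_numpy()

    # PCP random intercepts for the adherence model, in roster order.
    u = rng.normal(0.0, config.adherence_model.pcp_sd, size=len(pcps))
    pcp_info["u_pcp"] = u

    ep = patients.merge(pcp_info, on="pcp_id", how="left")
    if config.episodes_per_patient != 1:
        ep = ep.loc[ep.index.repeat(config.episodes_per_patient)].reset_index(drop=True)
    n = len(ep)
    if n == 0:
        return _empty_claims()

    window_days = (config.study_end - config.study_start).days
    start = np.datetime64(pd.Timestamp(config.study_start), "ns")
    day = np.timedelta64(1, "D").astype("timedelta64[ns]")
    fill_offset_days = rng.integers(0, window_days + 1, size=n)
    index_date = start + fill_offset_days * day

    med_class = np.where(rng.random(n) < config.class_mix_arb, "ARB", "IS")
    interruptive = np.datetime64(pd.Timestamp(config.interruptive_start), "ns")
    period = _period_labels(
        index_date, ep["effective_activation"].to_numpy(), interruptive
    )

    p_pref = np.empty(n)
    for group in GROUPS:
        for per in PERIODS:
            for cls in CLASSES:
                mask = (
                    (ep["group"].to_numpy() == group)
                    & (period == per)
                    & (med_class == cls)
                )
                if mask.any():
                    p_pref[mask] = config.tier_probability(group, per, cls)
    tier = np.where(rng.random(n) < p_pref, "preferred", "nonpreferred")

    centers = np.array(
        [config.copay_model.centers[(c, t)] for c, t in zip(med_class, tier)]
    )
    sigma = config.copay_model.log_sd
    monthly_copay = centers * np.exp(
        sigma * rng.standard_normal(n) - 0.5 * sigma**2
    )

    doses_per_day = np.where(rng.random(n) < config.p_freq_gt_daily, 2.0, 1.0)
    am = config.adherence_model
    mu = am.expected_pdc(
        monthly_copay,
        (med_class == "IS").astype(float),
        ep["income"].to_numpy(),
        (doses_per_day > 1).astype(float),
    )
    target = _bounded_pdc_noise(mu + ep["u_pcp"].to_numpy(), am.residual_sd, rng)
    # One fill always exists, so realized PDC is floored at 30/180.
    target = np.clip(target, FILL_DAYS / PDC_WINDOW_DAYS, 1.0)
    covered = np.rint(target * PDC_WINDOW_DAYS).astype(int)

    # Expand episodes into fill rows: n_full back-to-back 30-day fills plus
    # an optional remainder fill at day 180 - rem.
    n_full, rem = np.divmod(covered, FILL_DAYS)
    n_claims = n_full + (rem > 0)
    ep_idx = np.repeat(np.arange(n), n_claims)
    rank = np.arange(len(ep_idx)) - np.repeat(
        np.concatenate(([0], np.cumsum(n_claims)[:-1])), n_claims
    )
    offsets = np.where(
        rank < n_full[ep_idx],
        rank * FILL_DAYS,
        PDC_WINDOW_DAYS - rem[ep_idx],
    )
    fill_date = index_date[ep_idx] + offsets * day

    claims = pd.DataFrame(
        {
            "patient_id": ep["patient_id"].to_numpy()[ep_idx],
            "pcp_id": ep["pcp_id"].to_numpy()[ep_idx],
            "med_class": med_class[ep_idx],
            "tier": tier[ep_idx],
            "fill_date": fill_date,
            "days_supplied": FILL_DAYS,
            # 30-day fills: the claim copayment equals the monthly copayment.
            "copayment_dollars": monthly_copay[ep_idx] * (FILL_DAYS / 30.0),
            "doses_per_day": doses_per_day[ep_idx],
        }
    )
    end = np.datetime64(pd.Timestamp(config.study_end), "ns")
    claims = claims[claims["fill_date"].to_numpy() <= end].reset_index(drop=True)
    claims = claims.sort_values(
        ["patient_id", "med_class", "fill_date"], kind="mergesort"
    ).reset_index(drop=True)
    claims.insert(0, "claim_id", [f"C{i + 1:08d}" for i in range(len(claims))])
    return claims


def _empty_claims() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "claim_id": pd.Series(dtype=object),
            "patient_id": pd.Series(dtype=object),
            "pcp_id": pd.Series(dtype=object),
            "med_class": pd.Series(dtype=object),
            "tier": pd.Series(dtype=object),
            "fill_date": pd.Series(dtype="datetime64[ns]"),
            "days_supplied": pd.Series(dtype=int),
            "copayment_dollars": pd.Series(dtype=float),
            "doses_per_day": pd.Series(dtype=float),
        }
    )


def generate_adherence_records(
    config: SimulationConfig,
    n_records: int,
    n_pcps: int,
    rng: np.random.Generator,
    p_preferred: float = 0.65,
) -> pd.DataFrame:
    """Record-level adherence data (no claims realization).

    Draws covariates, monthly copayment, PCP random intercepts and residual
    noise and returns one row per index claim with its PDC clipped to
    [0, 1].  This is the direct route to the copayment:adherence model,
    free of the one-fill floor that claims realization imposes.
    """
    config.validate()
    am = config.adherence_model
    pcp_ids = np.array([f"P{i + 1:05d}" for i in range(n_pcps)], dtype=object)
    u = rng.normal(0.0, am.pcp_sd, size=n_pcps)
    assignment = rng.integers(0, n_pcps, size=n_records)

    med_class = np.where(rng.random(n_records) < config.class_mix_arb, "ARB", "IS")
    tier = np.where(rng.random(n_records) < p_preferred, "preferred", "nonpreferred")
    centers = np.array(
        [config.copay_model.centers[(c, t)] for c, t in zip(med_class, tier)]
    )
    sigma = config.copay_model.log_sd
    copay = centers * np.exp(sigma * rng.standard_normal(n_records) - 0.5 * sigma**2)
    income = rng.choice(
        np.array(INCOME_STRATA, dtype=object),
        size=n_records,
        p=[config.income_mix[s] for s in INCOME_STRATA],
    )
    freq = (rng.random(n_records) < config.p_freq_gt_daily).astype(float)
    mu = am.expected_pdc(copay, (med_class == "IS").astype(float), income, freq)
    pdc = _bounded_pdc_noise(mu + u[assignment], am.residual_sd, rng)
    return pd.DataFrame(
        {
            "pcp_id": pcp_ids[assignment],
            "med_class": med_class,
            "tier": tier,
            "monthly_copayment": copay,
            "income": income,
            "doses_per_day": 1.0 + freq,
            "pdc": pdc,
        }
    )


def true_parameters(config: SimulationConfig) -> dict:
    """Generator ground truth, keyed like the fitted-model output.

    Odds ratios are derived from the configured ARB tier cells (the IS
    cells share the same logit-scale structure when the configuration was
    built by the provided calibrators); the class odds ratio comes from the
    baseline cell.  If the configured cells are not log-additive across
    classes the ARB-scale ratios are reported and a warning is issued.
    """
    config.validate()

    def odds(group, period, cls):
        p = config.tier_probability(group, period, cls)
        if p <= 0.0 or p >= 1.0:
            raise ValueError(f"degenerate tier probability in cell {(group, period, cls)}")
        return p / (1.0 - p)

    base = odds("non", "pre", "ARB")
    fds_tier = {"class_is": odds("non", "pre", "IS") / base}
    for group in ("low", "high"):
        fds_tier[group] = odds(group, "pre", "ARB") / base
    for period in ("noninterruptive_only", "both_fds"):
        fds_tier[period] = odds("non", period, "ARB") / base
    for group in ("low", "high"):
        for period in ("noninterruptive_only", "both_fds"):
            fds_tier[f"{group}_x_{period}"] = (
                odds(group, period, "ARB")
                * base
                / (odds(group, "pre", "ARB") * odds("non", period, "ARB"))
            )
    # Cross-class additivity check.
    is_ratios = [
        odds(g, p, "IS") / odds(g, p, "ARB") for g in GROUPS for p in PERIODS
    ]
    if np.ptp(np.log(is_ratios)) > 1e-6:
        warnings.warn(
            "tier cells are not log-additive across classes; "
            "reported odds ratios are on the ARB scale",
            stacklevel=2,
        )

    centers = config.copay_model.centers
    tier_copay = {
        "cells": {f"{c}_{t}": centers[(c, t)] for (c, t) in centers},
        "tier_difference": {
            c: centers[(c, "nonpreferred")] - centers[(c, "preferred")]
            for c in CLASSES
        },
    }
    am = config.adherence_model
    copay_adherence = {
        "intercept": am.intercept,
        "copay_q_slope": am.copay_q_slope,
        "is_offset": am.is_offset,
        "income_45_75k": am.income_offsets.get("45-75k", 0.0),
        "income_ge_75k": am.income_offsets.get(">=75k", 0.0),
        "freq_gt_daily": am.freq_gt_daily_offset,
        "pcp_sd": am.pcp_sd,
        "residual_sd": am.residual_sd,
    }
    return {
        "fds_tier": fds_tier,
        "tier_copay": tier_copay,
        "boxcox_lambda": 0.25,
        "copay_adherence": copay_adherence,
    }


def write_tables(
    outdir, pcps: pd.DataFrame, patients: pd.DataFrame, claims: pd.DataFrame
) -> None:
    """Write pcps.csv / patients.csv / claims.csv with ISO-8601 dates."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pcps = pcps.copy()
    for col in ("activation_date", "synthetic_activation_date"):
        pcps[col] = pd.to_datetime(pcps[col]).dt.strftime("%Y-%m-%d")
    pcps.to_csv(outdir / "pcps.csv", index=False)
    patients.to_csv(outdir / "patients.csv", index=False)
    claims = claims.copy()
    claims["fill_date"] = pd.to_datetime(claims["fill_date"]).dt.strftime("%Y-%m-%d")
    claims.to_csv(outdir / "claims.csv", index=False)


def read_tables(indir) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read the three CSV tables written by :func:`write_tables`."""
    from pathlib import Path

    indir = Path(indir)
    pcps = pd.read_csv(
        indir / "pcps.csv",
        parse_dates=["activation_date", "synthetic_activation_date"],
    )
    patients = pd.read_csv(indir / "patients.csv")
    claims = pd.read_csv(indir / "claims.csv", parse_dates=["fill_date"])
    return pcps, patients, claims
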