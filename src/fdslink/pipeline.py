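"""End-to-end orchestration: simulate, cohort, PDC, fit, project.

``run_pipeline`` wires the library stages together and writes report-style
outputs into a directory:

* ``pcps.csv`` / ``patients.csv`` / ``claims.csv`` — generated tables;
* ``cohort.csv`` — labeled index claims; ``pdc.csv`` — adherence records;
* ``table2.csv`` — unadjusted percent-preferred by group x period;
* ``table3.csv`` — FDS:tier odds ratios; ``table4.csv`` — adherence
  coefficients;
* ``estimates.json`` — all fitted link estimates;
* ``projections.json`` — chained copayment/PDC projections (internal and
  external-benchmark routes);
* ``manifest.json`` — config hash, seed, exclusion-cascade counts,
  versions, timestamps.

All numeric outputs are deterministic given the config and seed (the
manifest's timestamp is the only run-varying field).  The report layer
performs no computation of its own.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .adherence import compute_pdc_table
from .cohort import build_cohort
from .config import CLASSES, SimulationConfig
from .models import (
    ModelEstimates,
    boxcox_select,
    fit_copay_adherence,
    fit_fds_tier,
    fit_tier_copay,
    summarize_unadjusted,
)
from .projection import ProjectionInput, net_probability_shift, project
from .simulate import generate_claims, generate_rosters, write_tables

logger = logging.getLogger("fdslink")


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-10s %.2fs", name, t1 - t0)
    return t1


def net_tier_shift_from_estimates(estimates: ModelEstimates) -> dict[str, float]:
    """Per-class preferred-probability increase attributable to the
    high-user x interruptive interaction.

    Baseline is the joint model's counterfactual prediction for the
    (high user, both-FDS) cell with the interaction term removed; the
    shift is the back-transformed difference after multiplying the odds by
    the interaction odds ratio.
    """
    ft = estimates.fds_tier
    needed = {"baseline_log_odds", "class_is", "high", "both_fds", "high_x_both_fds"}
    if not needed <= set(ft):
        return {}
    eta0 = ft["baseline_log_odds"]
    shifts = {}
    for cls in CLASSES:
        eta = eta0
        if cls == "IS":
            eta += np.log(ft["class_is"]["odds_ratio"])
        eta += np.log(ft["high"]["odds_ratio"])
        eta += np.log(ft["both_fds"]["odds_ratio"])
        baseline = float(1.0 / (1.0 + np.exp(-eta)))
        or_int = ft["high_x_both_fds"]["odds_ratio"]
        shifts[cls] = net_probability_shift(or_int, baseline)
    return shifts


def build_projections(estimates: ModelEstimates) -> dict:
    """Chain the fitted links into copayment and adherence projections."""
    slope = estimates.copay_adherence["copay_q_slope"]["estimate"]
    shifts = net_tier_shift_from_estimates(estimates)
    cells = estimates.tier_copay["cells"]
    out: dict = {"by_class": {}, "external": {}}
    if not shifts:
        out["note"] = (
            "high-user x both-FDS interaction not estimable "
            "(cell unpopulated); no tier-shift projection"
        )
        return out
    for cls in CLASSES:
        pref = cells[f"{cls}_preferred"]
        nonpref = cells[f"{cls}_nonpreferred"]
        res = project(
            ProjectionInput(
                delta_p=shifts[cls],
                copay_preferred=pref,
                copay_nonpreferred=nonpref,
                copay_slope=slope,
            )
        )
        out["by_class"][cls] = res.to_dict()
    # External benchmark: survey copayments + elasticity midrange.
    res_ext = project(
        ProjectionInput(
            delta_p=shifts["ARB"],
            copay_preferred=29.0,
            copay_nonpreferred=52.0,
            copay_slope=slope,
        )
    )
    out["external"] = res_ext.to_dict()
    return out


def run_pipeline(
    config: SimulationConfig | str | Path,
    out_dir: str | Path,
    seed: int | None = None,
    overlap: str = "shift",
) -> dict:
    """Run the whole analysis on freshly simulated claims.

    ``config`` may be a :class:`SimulationConfig` or a path to its YAML
    form.  ``seed`` overrides the config seed and must be set in one of
    the two.  Returns a summary dict with the manifest and estimates.
    """
    if not isinstance(config, SimulationConfig):
        config = SimulationConfig.from_yaml(config)
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("a seed is required (config.seed or the seed argument)")
    config.validate()

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    t0 = time.perf_counter()

    # --- simulate -------------------------------------------------------
    pcps, patients = generate_rosters(config, rng)
    claims = generate_claims(config, pcps, patients, rng)
    write_tables(out_dir, pcps, patients, claims)
    t0 = _stage("simulate", t0)

    # --- cohort ---------------------------------------------------------
    cohort, counts = build_cohort(
        claims,
        pcps,
        rng=rng,
        interruptive_start=config.interruptive_start,
    )
    cohort_out = cohort.copy()
    cohort_out["fill_date"] = pd.to_datetime(cohort_out["fill_date"]).dt.strftime(
        "%Y-%m-%d"
    )
    cohort_out.to_csv(out_dir / "cohort.csv", index=False)
    with open(out_dir / "exclusions.json", "w") as fh:
        json.dump(counts, fh, indent=2)
    t0 = _stage("cohort", t0)

    # --- adherence ------------------------------------------------------
    pdc = compute_pdc_table(
        cohort, claims, overlap=overlap, data_end=config.study_end
    )
    pdc = pdc.merge(patients[["patient_id", "income"]], on="patient_id", how="left")
    pdc_out = pdc[
        [
            "claim_id",
            "patient_id",
            "pcp_id",
            "med_class",
            "tier",
            "period",
            "group",
            "monthly_copayment",
            "income",
            "doses_per_day",
            "covered_days",
            "pdc",
            "right_censored",
        ]
    ]
    pdc_out.to_csv(out_dir / "pdc.csv", index=False)
    t0 = _stage("pdc", t0)

    # --- models ---------------------------------------------------------
    estimates = ModelEstimates()
    tier_part = fit_fds_tier(cohort)
    estimates.fds_tier = tier_part.fds_tier
    copay_part = fit_tier_copay(cohort)
    estimates.tier_copay = copay_part.tier_copay
    adjust = pd.DataFrame(
        {
            "is_class": (pdc["med_class"] == "IS").astype(float),
            "inc_mid": (pdc["income"] == "45-75k").astype(float),
            "inc_high": (pdc["income"] == ">=75k").astype(float),
            "freq_gt_daily": (pdc["doses_per_day"] > 1).astype(float),
        }
    )
    lam = boxcox_select(
        pdc["monthly_copayment"].to_numpy(),
        response=pdc["pdc"].to_numpy(),
        covariates=adjust,
    )
    adh_part = fit_copay_adherence(pdc, lam=lam)
    estimates.boxcox_lambda = lam
    estimates.copay_adherence = adh_part.copay_adherence

    table2 = summarize_unadjusted(cohort)
    table2.to_csv(out_dir / "table2.csv")
    _write_table3(estimates, out_dir / "table3.csv")
    _write_table4(estimates, out_dir / "table4.csv")
    with open(out_dir / "estimates.json", "w") as fh:
        json.dump(estimates.to_dict(), fh, indent=2, sort_keys=True)
    t0 = _stage("fit", t0)

    # --- projections ----------------------------------------------------
    projections = build_projections(estimates)
    with open(out_dir / "projections.json", "w") as fh:
        json.dump(projections, fh, indent=2, sort_keys=True)
    t0 = _stage("project", t0)

    manifest = {
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": int(seed),
        "counts": counts,
        "versions": _versions(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {
        "manifest": manifest,
        "estimates": estimates.to_dict(),
        "projections": projections,
        "table2": table2,
    }


def _versions() -> dict[str, str]:
    import pandas
    import scipy
    import statsmodels

    return {
        "fdslink": __version__,
        "numpy": np.__version__,
        "pandas": pandas.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }


def _write_table3(estimates: ModelEstimates, path: Path) -> None:
    rows = []
    order = [
        ("class_is", "Medication class - inhaled steroid"),
        ("low", "Low users (<30% of time)"),
        ("high", "High users (>=30% of time)"),
        ("noninterruptive_only", "Non-interruptive FDS time period"),
        ("both_fds", "Interruptive and non-interruptive FDS time period"),
        ("low_x_noninterruptive_only", "Low users x non-interruptive only"),
        ("low_x_both_fds", "Low users x both FDS"),
        ("high_x_noninterruptive_only", "High users x non-interruptive only"),
        ("high_x_both_fds", "High users x both FDS"),
    ]
    for key, label in order:
        if key not in estimates.fds_tier:
            continue
        e = estimates.fds_tier[key]
        rows.append(
            {
                "effect": label,
                "odds_ratio": round(e["odds_ratio"], 2),
                "ci_low": round(e["ci_low"], 2),
                "ci_high": round(e["ci_high"], 2),
                "p_value": round(e["p_value"], 4),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def _write_table4(estimates: ModelEstimates, path: Path) -> None:
    labels = {
        "copay_q_slope": "Copayment in dollars ^ 1/4",
        "is_offset": "Medication class - inhaled steroid",
        "income_45_75k": "Income $45k-$75k",
        "income_ge_75k": "Income > $75k",
        "freq_gt_daily": "Dosing frequency greater than once daily",
    }
    rows = []
    for key, label in labels.items():
        e = estimates.copay_adherence.get(key)
        if not isinstance(e, dict):
            continue
        rows.append(
            {
                "characteristic": label,
                "absolute_pdc_change_percent": round(100.0 * e["estimate"], 1),
                "p_value": round(e["p_value"], 4),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def plot_trend(cohort: pd.DataFrame, path: str | Path) -> None:
    """Simple preferred-tier trend plot by user group over calendar time."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = cohort.copy()
    df["preferred"] = (df["tier"] == "preferred").astype(float)
    df["quarter"] = pd.to_datetime(df["fill_date"]).dt.to_period("Q").astype(str)
    trend = (
        df.groupby(["quarter", "group"], observed=True)["preferred"]
        .mean()
        .unstack("group")
    )
    ax = trend.plot(marker="o", figsize=(8, 4.5))
    ax.set_ylabel("proportion preferred tier")
    ax.set_xlabel("calendar quarter of index fill")
    ax.set_title("Unadjusted preferred-tier prescribing by usage group")
    ax.figure.tight_layout()
    ax.figure.savefig(path, dpi=120)
    plt.close(ax.figure)
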