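"""The three statistical links of the analysis.

1. **FDS:tier** — difference-in-differences logistic model for preferred-
   tier prescribing, estimated by generalized estimating equations (GEE)
   with a logit link, exchangeable working correlation within prescriber
   and robust standard errors.  Covariates: medication-class indicator,
   usage-group main effects, period main effects, and the group x period
   interactions; the effect of interest is the high-user x interruptive-
   period interaction.
2. **tier:copayment** — ordinary least squares of monthly copayment on
   tier, class and their interaction (so each class x tier cell mean is
   exactly representable); reported as per-cell estimates and per-class
   tier differences in dollars.
3. **copayment:adherence** — linear mixed model of the 180-day PDC
   (absolute proportion) on monthly copayment to a Box-Cox-selected power,
   class, income stratum and dosing frequency, with a prescriber random
   intercept (REML).

Plus the Box-Cox exponent search for the copayment variable and a
backward-elimination routine gated jointly on a p-value threshold and a
fit criterion (QIC for the GEE link, AIC for the mixed model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .config import CLASSES, GROUPS, PERIODS

DEFAULT_LAMBDA_GRID = (0.0, 0.25, 0.5, 1.0)


@dataclass
class ModelEstimates:
    """Fitted coefficients for the three links, JSON-serializable."""

    fds_tier: dict = field(default_factory=dict)
    tier_copay: dict = field(default_factory=dict)
    boxcox_lambda: float | None = None
    copay_adherence: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "fds_tier": self.fds_tier,
            "tier_copay": self.tier_copay,
            "boxcox_lambda": self.boxcox_lambda,
            "copay_adherence": self.copay_adherence,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelEstimates":
        return cls(
            fds_tier=d.get("fds_tier", {}),
            tier_copay=d.get("tier_copay", {}),
            boxcox_lambda=d.get("boxcox_lambda"),
            copay_adherence=d.get("copay_adherence", {}),
        )


# --------------------------------------------------------------- FDS : tier

_FDS_TIER_KEYS = {
    "C(med_class, Treatment('ARB'))[T.IS]": "class_is",
    "C(group, Treatment('non'))[T.low]": "low",
    "C(group, Treatment('non'))[T.high]": "high",
    "C(period, Treatment('pre'))[T.noninterruptive_only]": "noninterruptive_only",
    "C(period, Treatment('pre'))[T.both_fds]": "both_fds",
    "C(group, Treatment('non'))[T.low]:C(period, Treatment('pre'))[T.noninterruptive_only]": "low_x_noninterruptive_only",
    "C(group, Treatment('non'))[T.low]:C(period, Treatment('pre'))[T.both_fds]": "low_x_both_fds",
    "C(group, Treatment('non'))[T.high]:C(period, Treatment('pre'))[T.noninterruptive_only]": "high_x_noninterruptive_only",
    "C(group, Treatment('non'))[T.high]:C(period, Treatment('pre'))[T.both_fds]": "high_x_both_fds",
}

FDS_TIER_FORMULA = (
    "preferred ~ C(med_class, Treatment('ARB')) "
    "+ C(group, Treatment('non')) * C(period, Treatment('pre'))"
)


def fit_fds_tier(
    index_claims: pd.DataFrame, include_pediatric: bool = False
) -> ModelEstimates:
    """Clustered diff-in-diff logistic model of preferred-tier prescribing.

    Expects columns ``tier``, ``med_class``, ``group``, ``period`` and
    ``pcp_id``.  Group x period cells without claims have their
    interaction terms dropped with a warning naming the cell.  Returns odds
    ratios with robust 95% confidence intervals, keyed by effect name.

    ``include_pediatric`` adds a pediatric-prescriber indicator as a
    sensitivity covariate (requires a ``specialty`` column); the default
    model omits it because a small pediatric claim stratum can dominate
    the predicted cell probabilities.
    """
    df = index_claims.copy()
    df["preferred"] = (df["tier"] == "preferred").astype(float)
    formula = FDS_TIER_FORMULA
    if include_pediatric:
        if "specialty" not in df.columns:
            raise KeyError(
                "include_pediatric=True needs a 'specialty' column on the claims"
            )
        df["pediatric"] = (df["specialty"] == "pediatrics").astype(float)
        formula = formula + " + pediatric"

    empty_cells = []
    counts = df.groupby(["group", "period"], observed=True).size()
    for g in GROUPS:
        for p in PERIODS:
            if counts.get((g, p), 0) == 0:
                empty_cells.append((g, p))
    if empty_cells:
        warnings.warn(
            f"group x period cells without claims: {empty_cells}; "
            "their terms are dropped from the design",
            stacklevel=2,
        )

    y, X = patsy.dmatrices(formula, df, return_type="dataframe")
    # Drop all-zero columns (arise when a cell or level is unpopulated).
    keep = [c for c in X.columns if c == "Intercept" or X[c].abs().sum() > 0]
    X = X[keep]
    def _fit(cov_struct):
        model = sm.GEE(
            np.asarray(y).ravel(),
            X,
            groups=df["pcp_id"].to_numpy(),
            family=sm.families.Binomial(),
            cov_struct=cov_struct,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return model.fit()

    res = _fit(sm.cov_struct.Exchangeable())
    if not np.all(np.isfinite(np.asarray(res.params))):
        # the exchangeable correlation update can diverge on small,
        # sparsely populated clusters; the sandwich errors stay valid
        # under an independence working structure
        warnings.warn(
            "exchangeable GEE did not converge; refitting with an "
            "independence working correlation",
            stacklevel=2,
        )
        res = _fit(sm.cov_struct.Independence())
    if not np.all(np.isfinite(np.asarray(res.params))):
        raise RuntimeError("tier model failed to converge")
    ci = np.asarray(res.conf_int())
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    pvalues = np.asarray(res.pvalues)
    cols = list(X.columns)
    out: dict[str, dict] = {}
    keymap = dict(_FDS_TIER_KEYS)
    if include_pediatric:
        keymap["pediatric"] = "pediatric"
    for col, key in keymap.items():
        if col not in cols:
            continue
        i = cols.index(col)
        out[key] = {
            "odds_ratio": float(np.exp(params[i])),
            "ci_low": float(np.exp(ci[i, 0])),
            "ci_high": float(np.exp(ci[i, 1])),
            "p_value": float(pvalues[i]),
            "log_or_se": float(bse[i]),
        }
    out["baseline_log_odds"] = float(params[cols.index("Intercept")])
    return ModelEstimates(fds_tier=out)


# ---------------------------------------------------------- Box-Cox search


def _power_transform(x: np.ndarray, lam: float) -> np.ndarray:
    return np.log(x) if lam == 0 else x**lam


def boxcox_select(
    monthly_copayments: Sequence[float],
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    response: Sequence[float] | None = None,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> float:
    """Select the Box-Cox exponent for the copayment variable.

    With a ``response`` (the intended use): for each exponent in the grid,
    regress the response on ``copay**lambda`` (``log`` for 0) plus any
    ``covariates`` and pick the exponent minimizing root mean squared
    error — the model-fit criterion for transforming a skewed cost
    covariate.  Adjustment covariates matter: without them a confounder
    correlated with copayment (e.g. medication class) distorts the
    marginal shape the transform is fit to.  Without a response the
    classic Box-Cox profile log-likelihood for normality of the copayment
    itself is maximized on the grid.

    The ranking is invariant to rescaling the copayments by a positive
    constant.  Raises if any copayment is non-positive (shift the variable
    first).
    """
    x = np.asarray(monthly_copayments, dtype=float)
    grid = list(lambda_grid)
    if not grid:
        raise ValueError("lambda grid is empty")
    if np.any(x <= 0):
        raise ValueError(
            "copayments must be positive for a Box-Cox transform; "
            "add a small shift constant to zero copayments first"
        )
    if response is not None:
        y = np.asarray(response, dtype=float)
        extra = None
        if covariates is not None:
            extra = np.asarray(covariates, dtype=float)
            if extra.ndim == 1:
                extra = extra[:, None]
        best_lam, best_rmse = None, np.inf
        for lam in grid:
            t = _power_transform(x, lam)
            parts = [np.ones_like(t), t]
            if extra is not None:
                parts.append(extra)
            design = np.column_stack(parts)
            beta, *_ = np.linalg.lstsq(design, y, rcond=None)
            rmse = float(np.sqrt(np.mean((y - design @ beta) ** 2)))
            if rmse < best_rmse - 1e-12:
                best_lam, best_rmse = lam, rmse
        return float(best_lam)
    llf = [stats.boxcox_llf(lam, x) for lam in grid]
    return float(grid[int(np.argmax(llf))])


# ------------------------------------------------------- tier : copayment


def fit_tier_copay(index_claims: pd.DataFrame) -> ModelEstimates:
    """Linear model of monthly copayment on tier, class and tier x class.

    Returns fitted per-cell copayment estimates and per-class tier
    differences (non-preferred minus preferred) in dollars, with standard
    errors.  Falls back to a class-only model (with a warning) if only one
    tier is present.
    """
    df = index_claims.copy()
    if "monthly_copayment" not in df:
        raise KeyError("index claims need a 'monthly_copayment' column")
    tiers = sorted(df["tier"].unique())
    if len(tiers) < 2:
        warnings.warn(
            f"single tier {tiers} in data: fitting class-only copayment model",
            stacklevel=2,
        )
        res = smf.ols("monthly_copayment ~ C(med_class)", data=df).fit()
        cells = {
            f"{c}_{tiers[0]}": float(
                res.predict(pd.DataFrame({"med_class": [c]})).iloc[0]
            )
            for c in df["med_class"].unique()
        }
        return ModelEstimates(
            tier_copay={"cells": cells, "tier_difference": {}, "single_tier": True}
        )

    # robust (HC1) errors: cost noise is multiplicative, so residual
    # variance differs sharply across class x tier cells
    res = smf.ols(
        "monthly_copayment ~ C(med_class, Treatment('ARB')) "
        "* C(tier, Treatment('preferred'))",
        data=df,
    ).fit(cov_type="HC1")
    grid = pd.DataFrame(
        [(c, t) for c in CLASSES for t in ("preferred", "nonpreferred")],
        columns=["med_class", "tier"],
    )
    pred = res.predict(grid)
    cells = {
        f"{c}_{t}": float(v)
        for (c, t), v in zip(zip(grid["med_class"], grid["tier"]), pred)
    }
    names = list(res.params.index)
    tier_main = "C(tier, Treatment('preferred'))[T.nonpreferred]"
    inter = (
        "C(med_class, Treatment('ARB'))[T.IS]:"
        "C(tier, Treatment('preferred'))[T.nonpreferred]"
    )
    diff = {
        "ARB": {
            "estimate": float(res.params[tier_main]),
            "se": float(res.bse[tier_main]),
        }
    }
    if inter in names:
        L = np.zeros(len(names))
        L[names.index(tier_main)] = 1.0
        L[names.index(inter)] = 1.0
        t_test = res.t_test(L)
        diff["IS"] = {"estimate": float(t_test.effect[0]), "se": float(t_test.sd[0, 0])}
    return ModelEstimates(tier_copay={"cells": cells, "tier_difference": diff})


# --------------------------------------------------- copayment : adherence

ADHERENCE_FORMULA = (
    "pdc ~ copay_q + is_class + C(income, Treatment('<45k')) + freq_gt_daily"
)


def _adherence_frame(records: pd.DataFrame, lam: float) -> pd.DataFrame:
    df = records.copy()
    df["copay_q"] = _power_transform(df["monthly_copayment"].to_numpy(float), lam)
    df["is_class"] = (df["med_class"] == "IS").astype(float)
    df["freq_gt_daily"] = (df["doses_per_day"] > 1).astype(float)
    return df


def fit_copay_adherence(
    pdc_records: pd.DataFrame, lam: float = 0.25
) -> ModelEstimates:
    """Linear mixed model of PDC on transformed copayment and covariates.

    ``pdc_records`` needs ``pdc``, ``monthly_copayment``, ``med_class``,
    ``income``, ``doses_per_day`` and ``pcp_id``.  The prescriber random
    intercept is dropped (with a warning) when fewer than two prescribers
    are present.  Coefficients are absolute changes in PDC; the copayment
    coefficient is per unit of ``copay**lam``.
    """
    df = _adherence_frame(pdc_records, lam)
    n_pcps = df["pcp_id"].nunique()
    keymap = {
        "Intercept": "intercept",
        "copay_q": "copay_q_slope",
        "is_class": "is_offset",
        "C(income, Treatment('<45k'))[T.45-75k]": "income_45_75k",
        "C(income, Treatment('<45k'))[T.>=75k]": "income_ge_75k",
        "freq_gt_daily": "freq_gt_daily",
    }
    out: dict[str, dict | float] = {"lambda": lam, "n": int(len(df))}
    if n_pcps < 2:
        warnings.warn(
            "fewer than 2 prescribers: dropping the random intercept",
            stacklevel=2,
        )
        res = smf.ols(ADHERENCE_FORMULA, data=df).fit()
        params, bse, pvals = res.params, res.bse, res.pvalues
        ci = res.conf_int()
        out["pcp_var"] = 0.0
        out["residual_var"] = float(res.mse_resid)
    else:
        model = smf.mixedlm(ADHERENCE_FORMULA, data=df, groups=df["pcp_id"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=True)
        params, bse, pvals = res.params, res.bse, res.pvalues
        ci = res.conf_int()
        out["pcp_var"] = float(res.cov_re.iloc[0, 0])
        out["residual_var"] = float(res.scale)
    for name, key in keymap.items():
        if name in params.index:
            out[key] = {
                "estimate": float(params[name]),
                "se": float(bse[name]),
                "ci_low": float(ci.loc[name][0]),
                "ci_high": float(ci.loc[name][1]),
                "p_value": float(pvals[name]),
            }
    return ModelEstimates(boxcox_lambda=lam, copay_adherence=out)


# ------------------------------------------------------ backward selection


@dataclass
class ModelSpec:
    """A formula split into response and removable/protected terms."""

    response: str
    terms: list[str]
    protected: set[str] = field(default_factory=set)
    kind: str = "ols"  # 'ols' | 'gee' | 'mixedlm'
    groups: str | None = None

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.terms) if self.terms else "1"
        return f"{self.response} ~ {rhs}"


def _fit_spec(spec: ModelSpec, data: pd.DataFrame):
    if spec.kind == "ols":
        return smf.ols(spec.formula, data=data).fit()
    if spec.kind == "gee":
        return smf.gee(
            spec.formula,
            groups=spec.groups,
            data=data,
            family=sm.families.Binomial(),
            cov_struct=sm.cov_struct.Exchangeable(),
        ).fit()
    if spec.kind == "mixedlm":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return smf.mixedlm(
                spec.formula, data=data, groups=data[spec.groups]
            ).fit(reml=True)
    raise ValueError(f"unknown model kind {spec.kind!r}")


def _criterion(spec: ModelSpec, data: pd.DataFrame, result) -> float:
    """QIC for the GEE link, AIC (ML) for the mixed model, AIC for OLS."""
    if spec.kind == "gee":
        qic = result.qic()
        return float(qic[0] if isinstance(qic, tuple) else qic)
    if spec.kind == "mixedlm":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ml = smf.mixedlm(spec.formula, data=data, groups=data[spec.groups]).fit(
                reml=False
            )
        return float(ml.aic)
    return float(result.aic)


def _term_pvalues(result, terms: Sequence[str]) -> dict[str, float]:
    """Joint Wald p-value per formula term (multi-column terms pooled)."""
    design_info = result.model.data.design_info
    pvals = {}
    for term in terms:
        slices = [
            design_info.term_name_slices[t]
            for t in design_info.term_names
            if t == term
        ]
        if not slices:
            continue
        cols = list(range(*slices[0].indices(len(design_info.column_names))))
        # width must span *all* model parameters (a mixed model appends
        # variance components after the fixed effects)
        L = np.zeros((len(cols), len(np.asarray(result.params))))
        for row, col in enumerate(cols):
            L[row, col] = 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            wt = result.wald_test(L, scalar=True)
        pvals[term] = float(wt.pvalue)
    return pvals


def backward_select(
    spec: ModelSpec,
    data: pd.DataFrame,
    alpha: float = 0.05,
    criterion_check: bool = True,
) -> tuple[ModelSpec, object]:
    """Backward elimination gated on p-value and a fit criterion.

    Repeatedly drops the least significant removable term whose joint Wald
    p-value exceeds ``alpha``, but only if the fit criterion (QIC for GEE,
    AIC for the mixed model / OLS) does not worsen; protected terms are
    never candidates.  Deterministic given the data.  Returns the reduced
    spec and its fitted result.
    """
    current = ModelSpec(
        spec.response,
        list(spec.terms),
        set(spec.protected),
        spec.kind,
        spec.groups,
    )
    result = _fit_spec(current, data)
    crit = _criterion(current, data, result) if criterion_check else None
    while True:
        removable = [t for t in current.terms if t not in current.protected]
        if not removable:
            break
        pvals = _term_pvalues(result, removable)
        # alpha >= 1 means every removable term is a candidate
        candidates = {t: p for t, p in pvals.items() if p > alpha or alpha >= 1.0}
        if not candidates:
            break
        drop = max(candidates, key=candidates.get)
        trial = ModelSpec(
            current.response,
            [t for t in current.terms if t != drop],
            current.protected,
            current.kind,
            current.groups,
        )
        trial_result = _fit_spec(trial, data)
        if criterion_check:
            trial_crit = _criterion(trial, data, trial_result)
            if trial_crit > crit:
                break
            crit = trial_crit
        current, result = trial, trial_result
    return current, result


# ------------------------------------------------------- unadjusted table


def summarize_unadjusted(index_claims: pd.DataFrame) -> pd.DataFrame:
    """Group x period percent-preferred table with marginals and counts.

    Returns a table indexed by user group (plus ``All``) with one column
    pair per period (plus ``All``): ``percent_preferred`` and ``n``.
    Empty cells report NaN percent, not 0.
    """
    df = index_claims.copy()
    df["preferred"] = (df["tier"] == "preferred").astype(float)
    # groups appear only if represented; all three periods always shown
    # (an unpopulated period cell is undefined, not omitted)
    groups = [g for g in GROUPS if g in set(df["group"])] + ["All"]
    periods = list(PERIODS) + ["All"]
    pct = pd.DataFrame(index=groups, columns=periods, dtype=float)
    n = pd.DataFrame(0, index=groups, columns=periods, dtype=int)
    for g in groups:
        gmask = slice(None) if g == "All" else (df["group"] == g)
        sub_g = df if g == "All" else df[gmask]
        for p in periods:
            sub = sub_g if p == "All" else sub_g[sub_g["period"] == p]
            n.loc[g, p] = len(sub)
            pct.loc[g, p] = 100.0 * sub["preferred"].mean() if len(sub) else np.nan
    out = pd.concat({"percent_preferred": pct, "n": n}, axis=1)
    out.index.name = "group"
    return out
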