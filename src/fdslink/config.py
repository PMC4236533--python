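"""Study configuration for the synthetic claims generator and pipeline.

The configuration encodes the study conditions the analysis assumes: a
three-year claims window, two brand-only medication classes (angiotensin
receptor blockers, ARB, and inhaled steroids, IS), a two-brand-tier benefit
structure (preferred / non-preferred), prescriber e-prescribing usage groups
(non-user, low user <30%, high user >=30%), rolling 2005 activation dates,
and an interruptive formulary-decision-support (FDS) go-live date after
which e-prescribers see both non-interruptive tier symbols and interruptive
preferred-alternative alerts.

Tier choice is modelled on the logit scale.  Two calibrations of the
per-cell preferred-tier probabilities are provided:

``default_tier_probabilities``
    Cells built from the published difference-in-differences odds ratios
    (class OR 4.1; group/period main effects; high-user x interruptive
    interaction OR 1.9) with the intercept solved so that the pooled
    non-user pre-FDS preferred share is 63%.  Under this calibration the
    generator's true odds ratios are exactly the configured ones.

``tier_cells_from_pooled``
    Cells solved so that the *pooled* (class-mixed) preferred share in each
    user-group x period cell equals the published unadjusted percentage
    table exactly, holding the class odds ratio fixed.  Useful for
    end-to-end calibration checks against the unadjusted table.

The two calibrations are not identical because the unadjusted cell
percentages and the adjusted odds ratios come from different summaries of
the same data and are individually rounded.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping

import numpy as np
import yaml
from scipy.optimize import brentq
from scipy.special import expit

GROUPS = ("non", "low", "high")
PERIODS = ("pre", "noninterruptive_only", "both_fds")
CLASSES = ("ARB", "IS")
TIERS = ("preferred", "nonpreferred")
INCOME_STRATA = ("<45k", "45-75k", ">=75k")

#: Preferred-tier odds ratios of the difference-in-differences tier model,
#: relative to (non-user, pre-FDS, ARB).
DEFAULT_TIER_ODDS_RATIOS: dict[str, float] = {
    "class_is": 4.1,
    "low": 0.9,
    "high": 0.8,
    "noninterruptive_only": 1.1,
    "both_fds": 1.0,
    "low_x_noninterruptive_only": 0.9,
    "low_x_both_fds": 0.8,
    "high_x_noninterruptive_only": 0.9,
    "high_x_both_fds": 1.9,
}

#: Unadjusted percent-preferred cells, group x period, pooled over classes.
POOLED_PREFERRED_SHARE: dict[tuple[str, str], float] = {
    ("non", "pre"): 0.63,
    ("non", "noninterruptive_only"): 0.69,
    ("non", "both_fds"): 0.70,
    ("low", "pre"): 0.59,
    ("low", "noninterruptive_only"): 0.60,
    ("low", "both_fds"): 0.61,
    ("high", "pre"): 0.57,
    ("high", "noninterruptive_only"): 0.61,
    ("high", "both_fds"): 0.78,
}

#: Monthly copayment centers in dollars per 30-day supply, class x tier.
DEFAULT_COPAY_CENTERS: dict[tuple[str, str], float] = {
    ("ARB", "preferred"): 10.60,
    ("ARB", "nonpreferred"): 11.81,
    ("IS", "preferred"): 14.86,
    ("IS", "nonpreferred"): 16.42,
}


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _pooled_share(eta_arb: float, log_class_or: float, arb_share: float) -> float:
    """Class-mixed preferred share for a cell with ARB linear predictor eta."""
    return arb_share * expit(eta_arb) + (1.0 - arb_share) * expit(eta_arb + log_class_or)


def _solve_eta(target: float, log_class_or: float, arb_share: float) -> float:
    """Invert the pooled share for the ARB-scale linear predictor."""
    return brentq(
        lambda eta: _pooled_share(eta, log_class_or, arb_share) - target, -20.0, 20.0
    )


def default_tier_probabilities(
    odds_ratios: Mapping[str, float] | None = None,
    baseline_pooled: float = 0.63,
    arb_share: float = 0.73,
) -> dict[tuple[str, str, str], float]:
    """Tier cells implied by the diff-in-diff odds ratios.

    The intercept (non-user, pre-FDS, ARB log-odds) is solved so the pooled
    baseline cell matches ``baseline_pooled``; every other cell follows from
    the log-additive odds-ratio structure, so the generator's true odds
    ratios equal ``odds_ratios`` exactly.
    """
    ors = dict(DEFAULT_TIER_ODDS_RATIOS if odds_ratios is None else odds_ratios)
    log_is = np.log(ors["class_is"])
    beta0 = _solve_eta(baseline_pooled, log_is, arb_share)
    cells: dict[tuple[str, str, str], float] = {}
    for group in GROUPS:
        for period in PERIODS:
            eta = beta0
            if group != "non":
                eta += np.log(ors[group])
            if period != "pre":
                eta += np.log(ors[period])
            if group != "non" and period != "pre":
                eta += np.log(ors[f"{group}_x_{period}"])
            cells[(group, period, "ARB")] = float(expit(eta))
            cells[(group, period, "IS")] = float(expit(eta + log_is))
    return cells


def tier_cells_from_pooled(
    pooled: Mapping[tuple[str, str], float] | None = None,
    class_or: float = 4.1,
    arb_share: float = 0.73,
) -> dict[tuple[str, str, str], float]:
    """Tier cells whose class-mixed share reproduces the unadjusted table.

    Each group x period cell's ARB linear predictor is solved so that the
    ARB/IS mixture (IS on the same logit scale shifted by ``log(class_or)``)
    equals the pooled target exactly.
    """
    pooled = dict(POOLED_PREFERRED_SHARE if pooled is None else pooled)
    log_is = float(np.log(class_or))
    cells: dict[tuple[str, str, str], float] = {}
    for (group, period), target in pooled.items():
        eta = _solve_eta(target, log_is, arb_share)
        cells[(group, period, "ARB")] = float(expit(eta))
        cells[(group, period, "IS")] = float(expit(eta + log_is))
    return cells


def default_activation_dates(n: int = 101) -> list[date]:
    """Empirical 2005 activation-date multiset.

    Piecewise-linear interpolation through the published adoption-date
    quartiles (Q1 2005-06-02, median 2005-08-04, Q3 2005-09-29) with tails
    at mid-January and mid-December 2005, reflecting rolling activation
    throughout calendar 2005.
    """
    anchors_q = [0.0, 0.25, 0.50, 0.75, 1.0]
    anchors_d = [
        date(2005, 1, 14),
        date(2005, 6, 2),
        date(2005, 8, 4),
        date(2005, 9, 29),
        date(2005, 12, 15),
    ]
    origin = date(2005, 1, 1)
    anchor_days = [(d - origin).days for d in anchors_d]
    qs = np.linspace(0.0, 1.0, n)
    days = np.interp(qs, anchors_q, anchor_days)
    return [origin + timedelta(days=int(round(d))) for d in days]


@dataclass
class CopayModel:
    """Monthly copayment distribution per medication class and tier.

    ``centers`` are dollars per 30-day supply and equal the cell *mean*:
    draws are center x exp(sigma Z - sigma^2/2), a mean-one multiplicative
    log-normal reproducing the right skew typical of cost data.  ``log_sd``
    of 0 degenerates to the centers exactly.
    """

    centers: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_COPAY_CENTERS)
    )
    log_sd: float = 0.25

    def validate(self) -> None:
        if self.log_sd < 0:
            raise ValueError("copay log_sd must be >= 0")
        for cls in CLASSES:
            for tier in TIERS:
                if (cls, tier) not in self.centers:
                    raise ValueError(f"copay center missing for cell ({cls}, {tier})")
                if self.centers[(cls, tier)] <= 0:
                    raise ValueError(f"copay center for ({cls}, {tier}) must be > 0")


@dataclass
class AdherenceModel:
    """Linear model for the 180-day proportion of days covered (PDC).

    PDC = intercept + copay_q_slope * copay^0.25 + is_offset * 1[IS]
          + income offsets + freq_gt_daily_offset * 1[dosing > once daily]
          + PCP random intercept + residual, clipped to [0, 1].

    Coefficients are absolute PDC changes.  The default intercept places
    the ARB / non-preferred-copay / lowest-income / once-daily profile at
    an expected PDC of 74.62%.
    """

    intercept: float = 0.8945
    copay_q_slope: float = -0.08
    is_offset: float = -0.49
    income_offsets: dict[str, float] = field(
        default_factory=lambda: {"45-75k": 0.06, ">=75k": 0.08}
    )
    freq_gt_daily_offset: float = -0.04
    pcp_sd: float = 0.05
    residual_sd: float = 0.10

    def validate(self) -> None:
        if self.pcp_sd < 0 or self.residual_sd < 0:
            raise ValueError("adherence model SDs must be >= 0")
        for stratum in self.income_offsets:
            if stratum not in INCOME_STRATA[1:]:
                raise ValueError(f"unknown income stratum {stratum!r}")

    def expected_pdc(
        self,
        monthly_copay: np.ndarray | float,
        is_class: np.ndarray | float,
        income: np.ndarray | str,
        freq_gt_daily: np.ndarray | float,
    ) -> np.ndarray:
        """Mean PDC for a covariate profile, clipped to [0, 1]."""
        copay = np.asarray(monthly_copay, dtype=float)
        inc = np.atleast_1d(np.asarray(income, dtype=object))
        inc_off = np.array([self.income_offsets.get(str(s), 0.0) for s in inc])
        mu = (
            self.intercept
            + self.copay_q_slope * copay**0.25
            + self.is_offset * np.asarray(is_class, dtype=float)
            + inc_off
            + self.freq_gt_daily_offset * np.asarray(freq_gt_daily, dtype=float)
        )
        out = np.clip(mu, 0.0, 1.0)
        if np.ndim(monthly_copay) == 0 and isinstance(income, str):
            return float(np.asarray(out).ravel()[0])
        return out


@dataclass
class SimulationConfig:
    """Full generator configuration; defaults are the study conditions."""

    n_pcps_per_group: dict[str, int] = field(
        default_factory=lambda: {"non": 1570, "low": 187, "high": 74}
    )
    patients_per_pcp: int = 8
    study_start: date = date(2003, 6, 3)
    study_end: date = date(2006, 7, 21)
    interruptive_start: date = date(2005, 9, 16)
    activation_dates: list[date] = field(default_factory=default_activation_dates)
    class_mix_arb: float = 0.73
    tier_probabilities: dict[tuple[str, str, str], float] = field(
        default_factory=default_tier_probabilities
    )
    copay_model: CopayModel = field(default_factory=CopayModel)
    adherence_model: AdherenceModel = field(default_factory=AdherenceModel)
    income_mix: dict[str, float] = field(
        default_factory=lambda: {"<45k": 0.18, "45-75k": 0.58, ">=75k": 0.24}
    )
    p_female: float = 0.52
    age_mean: float = 45.8
    age_sd: float = 19.5
    p_freq_gt_daily: float = 0.12
    low_usage_range: tuple[float, float] = (0.01, 0.30)
    #: high-group usage = 0.30 + 0.70 * Beta(a, b); defaults give mean 0.61.
    high_usage_beta: tuple[float, float] = (2.0, 2.515)
    episodes_per_patient: int = 1
    seed: int | None = None

    def validate(self) -> None:
        for group in GROUPS:
            if self.n_pcps_per_group.get(group, 0) < 0:
                raise ValueError("group counts must be >= 0")
        if all(self.n_pcps_per_group.get(g, 0) == 0 for g in GROUPS):
            raise ValueError("at least one prescriber group must be non-empty")
        if self.patients_per_pcp < 0 or self.episodes_per_patient < 0:
            raise ValueError("counts must be >= 0")
        if not self.study_start < self.study_end:
            raise ValueError("study window is empty")
        if not self.activation_dates:
            raise ValueError("activation_date distribution is empty")
        for d in self.activation_dates:
            if d.year != 2005:
                raise ValueError("activation dates must fall within calendar 2005")
        if not 0.0 <= self.class_mix_arb <= 1.0:
            raise ValueError("class_mix_arb must be a probability")
        for key, p in self.tier_probabilities.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"tier probability for cell {key} outside [0, 1]")
        probs = list(self.income_mix.values()) + [self.p_female, self.p_freq_gt_daily]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.income_mix.values()) - 1.0) > 1e-8:
            raise ValueError("income mix must sum to 1")
        lo, hi = self.low_usage_range
        if not 0.0 <= lo <= hi <= 0.30:
            raise ValueError("low-user usage range must lie within [0, 0.30]")
        self.copay_model.validate()
        self.adherence_model.validate()

    def tier_probability(self, group: str, period: str, med_class: str) -> float:
        try:
            return self.tier_probabilities[(group, period, med_class)]
        except KeyError:
            raise KeyError(
                f"no preferred-tier probability configured for cell "
                f"(group={group!r}, period={period!r}, class={med_class!r})"
            ) from None

    # ------------------------------------------------------------------ I/O
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["study_start"] = self.study_start.isoformat()
        d["study_end"] = self.study_end.isoformat()
        d["interruptive_start"] = self.interruptive_start.isoformat()
        d["activation_dates"] = [x.isoformat() for x in self.activation_dates]
        d["tier_probabilities"] = {
            group: {
                period: {
                    cls: self.tier_probabilities[(group, period, cls)]
                    for cls in CLASSES
                    if (group, period, cls) in self.tier_probabilities
                }
                for period in PERIODS
            }
            for group in GROUPS
        }
        d["copay_model"]["centers"] = {
            cls: {
                tier: self.copay_model.centers[(cls, tier)]
                for tier in TIERS
                if (cls, tier) in self.copay_model.centers
            }
            for cls in CLASSES
        }
        d["low_usage_range"] = list(self.low_usage_range)
        d["high_usage_beta"] = list(self.high_usage_beta)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("study_start", "study_end", "interruptive_start"):
            if isinstance(d.get(key), str):
                d[key] = date.fromisoformat(d[key])
        if "activation_dates" in d:
            d["activation_dates"] = [
                date.fromisoformat(x) if isinstance(x, str) else x
                for x in d["activation_dates"]
            ]
        if "tier_probabilities" in d and isinstance(d["tier_probabilities"], dict):
            flat_keys = all(isinstance(k, tuple) for k in d["tier_probabilities"])
            if not flat_keys:
                d["tier_probabilities"] = {
                    (g, p, c): float(pv)
                    for g, by_period in d["tier_probabilities"].items()
                    for p, by_cls in by_period.items()
                    for c, pv in by_cls.items()
                }
        if "copay_model" in d and isinstance(d["copay_model"], dict):
            cm = dict(d["copay_model"])
            centers = cm.get("centers", {})
            if centers and not all(isinstance(k, tuple) for k in centers):
                cm["centers"] = {
                    (c, t): float(v)
                    for c, by_tier in centers.items()
                    for t, v in by_tier.items()
                }
            d["copay_model"] = CopayModel(**cm)
        if "adherence_model" in d and isinstance(d["adherence_model"], dict):
            d["adherence_model"] = AdherenceModel(**d["adherence_model"])
        if "low_usage_range" in d:
            d["low_usage_range"] = tuple(d["low_usage_range"])
        if "high_usage_beta" in d:
            d["high_usage_beta"] = tuple(d["high_usage_beta"])
        config = cls(**d)
        config.validate()
        return config

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
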