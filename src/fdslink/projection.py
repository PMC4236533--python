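"""Chained effect projections: FDS -> tier -> copayment -> adherence.

These calculators combine the three fitted links (or external benchmark
constants) into projected copayment and adherence effects:

* a shift of ``delta_p`` probability mass from the non-preferred to the
  preferred tier changes the expected monthly copayment by
  ``-delta_p * (c_non - c_pref)``;
* a copayment change moves the expected PDC along the fitted
  ``copay**0.25`` slope;
* alternatively, a cost-sharing elasticity (midrange 0.4: a 4% use
  decrease per 10% out-of-pocket increase) converts a *relative* copayment
  change into an absolute PDC change from a baseline PDC.

External benchmark constants: national survey copayments of $29 preferred
/ $52 non-preferred (2013) and $23 / $40 (2005, era-matched to the study
window), against the study's own observed ~$1.21-$1.56 tier differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: National-survey monthly copayments (preferred, non-preferred) by year.
SURVEY_COPAY = {2013: (29.0, 52.0), 2005: (23.0, 40.0)}

#: Cost-sharing elasticity: (low, midrange, high) adherence response per
#: unit relative cost change (2%-6% per 10%, midrange 4% per 10%).
GOLDMAN_ELASTICITY = (0.2, 0.4, 0.6)


def expected_copay_change(
    delta_p: float, copay_preferred: float, copay_nonpreferred: float
) -> float:
    """Expected monthly copayment reduction from a tier shift, in dollars.

    ``c_non - [delta_p * c_pref + (1 - delta_p) * c_non]``, i.e.
    ``delta_p * (c_non - c_pref)``: the expected copayment before minus
    after moving ``delta_p`` of prescriptions to the preferred tier.
    Rounded to cents.
    """
    if not 0.0 <= delta_p <= 1.0:
        raise ValueError("delta_p must lie in [0, 1]")
    expected_after = delta_p * copay_preferred + (1.0 - delta_p) * copay_nonpreferred
    return round(copay_nonpreferred - expected_after, 2)


def pdc_change_from_copay(
    copay_slope: float, base_copay: float, new_copay: float, lam: float = 0.25
) -> float:
    """Absolute PDC change when copayment moves from base to new.

    ``copay_slope * (new**lam - base**lam)``; with the negative fitted
    slope a copayment decrease yields a positive PDC change.  Returned as
    an absolute proportion (0.0006 = 0.06 percentage points).
    """
    if base_copay <= 0 or new_copay <= 0:
        raise ValueError("copayments must be positive")
    return copay_slope * (new_copay**lam - base_copay**lam)


def elasticity_projection(
    base_pdc: float, elasticity: float, relative_copay_change: float
) -> float:
    """Absolute PDC change under a proportional-response elasticity model.

    ``base_pdc * elasticity * (-relative_copay_change)``: a negative
    relative copayment change (a saving) raises adherence.  With the
    midrange elasticity 0.4, a 15% copayment reduction from a 60% baseline
    PDC projects a +3.6 percentage-point PDC gain.
    """
    if not 0.0 <= base_pdc <= 1.0:
        raise ValueError("base_pdc must lie in [0, 1]")
    if elasticity < 0:
        raise ValueError("elasticity must be >= 0")
    return base_pdc * elasticity * (-relative_copay_change)


def net_probability_shift(odds_ratio: float, baseline_probability: float) -> float:
    """Absolute probability increase implied by an odds ratio.

    Converts the baseline to odds, multiplies by the odds ratio and
    back-transforms; returns new minus baseline probability.
    """
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")
    if not 0.0 < baseline_probability < 1.0:
        raise ValueError("baseline probability must lie strictly in (0, 1)")
    odds = baseline_probability / (1.0 - baseline_probability) * odds_ratio
    return odds / (1.0 + odds) - baseline_probability


@dataclass
class ProjectionInput:
    """Inputs of one chained projection."""

    delta_p: float
    copay_preferred: float
    copay_nonpreferred: float
    copay_slope: float = -0.08
    base_copay: float | None = None
    base_pdc: float = 0.60
    elasticity: float = GOLDMAN_ELASTICITY[1]
    #: denominator for the relative copayment change in the elasticity
    #: route; era-matched preferred survey copayment by default.
    elasticity_base_copay: float = SURVEY_COPAY[2005][0]

    def validate(self) -> None:
        if not 0.0 <= self.delta_p <= 1.0:
            raise ValueError("delta_p must lie in [0, 1]")
        if self.copay_preferred <= 0 or self.copay_nonpreferred <= 0:
            raise ValueError("copayments must be positive")
        if not 0.0 <= self.base_pdc <= 1.0:
            raise ValueError("base_pdc must lie in [0, 1]")
        if self.elasticity < 0:
            raise ValueError("elasticity must be >= 0")


@dataclass
class ProjectionResult:
    """Chained copayment and PDC effects with their input assumptions."""

    expected_copay_change: float
    pdc_change_internal: float
    pdc_change_external: float
    assumptions: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "expected_copay_change": self.expected_copay_change,
            "pdc_change_internal": self.pdc_change_internal,
            "pdc_change_external": self.pdc_change_external,
            "assumptions": self.assumptions,
        }


def project(inputs: ProjectionInput) -> ProjectionResult:
    """Run the full chain from a tier-probability shift.

    ``pdc_change_internal`` moves the expected copayment down by the
    projected amount and follows the fitted ``copay**0.25`` slope from
    ``base_copay`` (the pre-shift expected copayment,
    ``(1 - delta_p) * c_non + delta_p * c_pref`` offset convention:
    default is the non-preferred copayment unless given).
    ``pdc_change_external`` applies the elasticity model to the relative
    copayment change against ``elasticity_base_copay``.
    """
    inputs.validate()
    d_copay = expected_copay_change(
        inputs.delta_p, inputs.copay_preferred, inputs.copay_nonpreferred
    )
    base = (
        inputs.base_copay
        if inputs.base_copay is not None
        else inputs.copay_nonpreferred
    )
    pdc_internal = pdc_change_from_copay(inputs.copay_slope, base, base - d_copay)
    pdc_external = elasticity_projection(
        inputs.base_pdc, inputs.elasticity, -d_copay / inputs.elasticity_base_copay
    )
    return ProjectionResult(
        expected_copay_change=d_copay,
        pdc_change_internal=pdc_internal,
        pdc_change_external=pdc_external,
        assumptions={
            "delta_p": inputs.delta_p,
            "copay_preferred": inputs.copay_preferred,
            "copay_nonpreferred": inputs.copay_nonpreferred,
            "copay_slope": inputs.copay_slope,
            "base_copay": base,
            "base_pdc": inputs.base_pdc,
            "elasticity": inputs.elasticity,
            "elasticity_base_copay": inputs.elasticity_base_copay,
        },
    )
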