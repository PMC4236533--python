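"""Chain the three links into copayment and adherence projections.

A 15-percentage-point shift toward the preferred tier (the estimated net
effect of interruptive alerts for ARB) is worth only $0.18/month at the
study's observed tier copayments, but $3.45/month at national-survey
copayments — the 'weak link' that explains why tier decision support did
not measurably move adherence in the studied plans.
"""

import fdslink as fl

# study-observed tier copayments
for cls, delta_p, pref, nonpref in (
    ("ARB", 0.15, 10.60, 11.81),
    ("IS", 0.08, 14.86, 16.42),
):
    d = fl.expected_copay_change(delta_p, pref, nonpref)
    print(f"{cls}: {delta_p:.0%} tier shift x (${nonpref} - ${pref}) "
          f"= ${d:.2f}/month saved")

# copayment -> adherence along the fitted copay^0.25 slope
gain = 100 * fl.pdc_change_from_copay(-0.08, 11.18, 11.00)
print(f"ARB $11.18 -> $11.00: PDC +{gain:.2f} percentage points")
within = 100 * fl.pdc_change_from_copay(-0.08, 11.81, 10.60)
print(f"moving one patient from non-preferred to preferred (ARB): "
      f"PDC +{within:.2f} percentage points")

# external benchmark: survey copayments ($29 / $52) + cost-sharing
# elasticity (4% per 10%, from a 60% baseline PDC)
ext = fl.project(
    fl.ProjectionInput(delta_p=0.15, copay_preferred=29.0, copay_nonpreferred=52.0)
)
print(f"survey copayments: ${ext.expected_copay_change:.2f}/month saved, "
      f"PDC +{100 * ext.pdc_change_external:.1f} percentage points "
      f"(elasticity route)")
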