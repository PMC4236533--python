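"""Generate a synthetic claims extract and build the new-user cohort.

Draws prescriber/patient rosters and a claims stream, then applies the
exclusion cascade (minimum 15 days supplied, 180-day same-class washout,
2006 adherence cutoff) and labels every index claim with its prescriber
usage group and FDS exposure period.
"""

import numpy as np

import fdslink as fl

config = fl.SimulationConfig(
    n_pcps_per_group={"non": 200, "low": 60, "high": 60},
    patients_per_pcp=10,
    seed=7,
)
rng = np.random.default_rng(config.seed)

pcps, patients = fl.generate_rosters(config, rng)
claims = fl.generate_claims(config, pcps, patients, rng)
cohort, counts = fl.build_cohort(
    claims, pcps, rng=rng, interruptive_start=config.interruptive_start
)

print("exclusion cascade:", counts)
print("\nindex claims per usage group and exposure period:")
print(cohort.groupby(["group", "period"]).size().unstack())

# Each row of the cascade shrinks: raw dispensings include refills; the
# washout keeps only new starts; pre-2006 starts have full follow-up.
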