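"""Proportion of days covered for hand-built refill patterns.

The PDC is the fraction of the 180 days after the index fill on which
same-class medication supply was available.  Overlapping fills are queued
forward by default (stockpiling); a `truncate` mode discards overlap.
"""

import pandas as pd

import fdslink as fl

index_claim = {"claim_id": "demo", "fill_date": pd.Timestamp("2004-01-01")}

# three refill scenarios: perfect, gappy, and overlapping
scenarios = {
    "six back-to-back 30-day fills": ["2004-01-01", "2004-01-31", "2004-03-01",
                                      "2004-03-31", "2004-04-30", "2004-05-30"],
    "one fill, no refills": ["2004-01-01"],
    "second fill 10 days early": ["2004-01-01", "2004-01-21"],
}

for name, dates in scenarios.items():
    fills = pd.DataFrame({"fill_date": pd.to_datetime(dates), "days_supplied": 30})
    shift = fl.compute_pdc(index_claim, fills, overlap="shift")
    trunc = fl.compute_pdc(index_claim, fills, overlap="truncate")
    print(f"{name}: PDC(shift) = {shift.pdc:.3f} "
          f"({shift.covered_days}/180 days), PDC(truncate) = {trunc.pdc:.3f}")

# shift vs truncate only differ when supplies overlap: the early refill
# is either banked for later (60 covered days) or partially wasted (50).
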