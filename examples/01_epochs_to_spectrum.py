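"""From 1-second epoch counts to a valid intensity spectrum.

Simulates four weekdays of triaxial accelerometer counts for one child
(including a forced 25-minute zero-count block), restricts each day to
preschool hours, removes non-wear, classifies wear epochs into the
traditional 4-class descriptor and checks the wear-time validity rules.
"""

import datetime as dt

from mvpatrial.accel import (
    DescriptorSpec, aggregate_child, detect_nonwear, restrict_window,
    summarize_day,
)
from mvpatrial.synth import EpochSimConfig, generate_epochs

spec = DescriptorSpec.traditional()
cfg = EpochSimConfig(forced_zero_minutes=25)
days = []
for series in generate_epochs(cfg, n_children=1, n_days=4, seed=3):
    series = restrict_window(series, dt.time(8, 30), dt.time(15, 30))
    mask = detect_nonwear(series, min_zero_minutes=20)
    day = summarize_day(series, mask, spec)
    days.append(day)
    nonwear = (~mask).sum() * series.epoch_len / 60
    print(f"{day.date} wear {day.wear_minutes:6.1f} min  non-wear {nonwear:5.1f} min")

child = aggregate_child(days, spec, timepoint="baseline")
print(f"\nvalid measurement: {child.valid} ({child.n_valid_days} valid weekdays"
      " with >= 300 min wear)")
if child.valid:
    print("mean min/day per intensity class (sums to mean wear time):")
    for name, v in child.values.items():
        print(f"  {name:4s} {v:7.1f}")
    print(f"  wear {child.wear_minutes:7.1f}")
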