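"""Simulate the default synthetic cluster trial and summarize it.

46 preschools randomized 1:1, ~15 children each, three waves, preschool
variance fraction 0.08, retention 78%/75%. Printed means/SDs should track
the descriptive calibration targets (e.g. baseline sedentary time
~284 (23) min/day in the intervention arm).
"""

from mvpatrial.synth import TrialConfig, generate_trial

table = generate_trial(TrialConfig(descriptors=("traditional",)), seed=1)
n = table["child_id"].nunique()
print(f"{n} children in {table['preschool_id'].nunique()} preschools, "
      f"{len(table)} child x timepoint rows")
for tp in ("baseline", "7mo", "18mo"):
    sub = table[table["timepoint"] == tp]
    print(f"  retained at {tp:8s}: {sub['child_id'].nunique():4d} "
          f"({100 * len(sub) / n:.0f}%)")

print("\narm x wave means (SD), min/day:")
for grp, name in ((1, "intervention"), (0, "control")):
    for tp in ("baseline", "7mo", "18mo"):
        s = table[(table["group"] == grp) & (table["timepoint"] == tp)]
        cells = "  ".join(
            f"{v}={s[v].mean():5.1f} ({s[v].std():4.1f})"
            for v in ("sed", "lpa", "mpa", "vpa")
        )
        print(f"  {name:12s} {tp:8s} {cells}")
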