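"""Evaluate the five-item rupture-risk checklist for one setting.

The slow-flow preset is an ideal dumbbell (C2/C1 = 1) with moderate
compliance: it should flag shape, size and pressure but not the thin-wall
items.
"""

import windkessel5 as wk

params = wk.PRESETS["fig6"]
traj, stats = wk.run_preset("fig6")
report = wk.risk_report(params, stats)

print(f"scenario classification: {report.scenario_notes}")
for key, item in report.to_checklist().items():
    mark = "FLAG" if item["flag"] else " ok "
    print(f"  [{mark}] {key:24s} value {item['quantity']:8.4g}  "
          f"border {item['threshold']:g}")
print(f"overall: {'AT RISK' if report.any_flag else 'no flags'}")

# Aspect ratio 1.73 > 1.6, daughter at 100% of the mother, and a daughter
# pressure above 180 mmHg: three independent rupture markers fire at once.
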