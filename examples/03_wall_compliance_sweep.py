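"""Thin the mother wall (raise L1) with a vestigial daughter and watch the
peak mother pressure grow linearly.

Single-sac setting: C1 = 0.1, C2 = 0.001, L2 = 0 (algebraic branch).
"""

import numpy as np

import windkessel5 as wk

sweep = wk.sweep_compliance(L1_grid=np.arange(0.0, 81.0, 10.0))

print("  L1    max P1 [mmHg]")
for L1, s in zip(sweep.values, sweep.stats):
    print(f"  {L1:4.0f}  {s.max_P1:8.2f}")

mask = sweep.values >= 20
coef = np.polyfit(sweep.values[mask], [s.max_P1 for s, m in zip(sweep.stats, mask) if m], 1)
print(f"\nlinear fit on L1 in [20, 80]: max P1 ~ {coef[0]:.3f} * L1 + {coef[1]:.1f}")

# A rigid wall (L1 = 0) just passes the 120 mmHg systolic input through;
# every extra unit of compliance adds ~6.7 mmHg of peak pressure, so even a
# small aneurysm with a thin, distensible wall reaches rupture pressures.
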