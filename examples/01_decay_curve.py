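"""Closed-form follicle decay curve and the median woman's menopause age.

Evaluates the expected reserve E[F(t)] = N * S(t) for the fitted human
parameters (D = 0.004/yr, V = 0.051/yr, starting supply 3.23e5) and finds
the age at which it crosses the 1,000-follicle menopause threshold.
"""

import numpy as np

from pfwalk import ContinuousParams, anm_from_curve, expected_reserve

params = ContinuousParams(D=0.004, V=0.051)
N = 3.23e5

for age in (0, 10, 20, 30, 40, 50, 60):
    f = expected_reserve(float(age), N, params)
    print(f"age {age:3d} yr   expected reserve {f:12.1f} follicles")

anm = anm_from_curve(N, params, threshold=1000.0)
print(f"\nthe curve crosses 1,000 follicles at {anm:.2f} yr "
      f"(rounded: {round(anm)}) — the model's median age at natural menopause")
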