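"""Time-variant drift: a one-time drift acceleration at age 38.

Once the drift changes mid-course no closed form exists for the reserve's
survival (the surviving follicles' activity positions matter), so the walk's
law is propagated exactly on its lattice. The example compares late-life
survival with and without the acceleration and simulates a population under
the accelerating schedule. Note that the 0.024/0.033 per-year drift pair
decays far more slowly than the single fitted drift of 0.051 per year, so
menopause ages under this schedule fall much later.
"""

import numpy as np

from pfwalk import ContinuousParams, DriftSchedule, schedule_survival, simulate_population

params = ContinuousParams()
accel = DriftSchedule.amh_acceleration()      # 0.024 /yr before 38, 0.033 after
flat = DriftSchedule.constant(0.024)

s_accel = schedule_survival(params, accel, max_age=100.0)
s_flat = schedule_survival(params, flat, max_age=100.0)
for age in (30, 38, 50, 70, 90):
    k = int(age * 48)  # internal 1/48-yr occupancy grid
    print(f"age {age:3d}: S = {s_accel[k]:.4f} accelerating, "
          f"{s_flat[k]:.4f} constant 0.024/yr")

res = simulate_population(2000, base_schedule=accel, c=0.03, seed=11,
                          keep_quantile_trajectories=False)
s = res.summary()
print(f"\npopulation of 2000 under the accelerating schedule: "
      f"median ANM {s['median_anm']:.1f} yr ({s['n_censored']} censored at 120)")
print("identical survival up to age 38, faster depletion after — the "
      "acceleration compresses the late tail of the reserve")
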