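"""Compare sulfate production kinetics under light and dark cultivation.

Simulates paired logistic time courses (dark production rate slowed to
40% of light), quantifies each time point through the calibration model,
and reports model-free kinetic statistics: the maximum sliding-window
production rate and the midpoint-crossing time.
"""

import ramanquant as rq
from ramanquant.synthetic import KineticProfile, NOISE_SD_MID

model = rq.CalibrationModel(slope=0.01802, intercept=-0.04239,
                            r_squared=0.99938, conc_range=(25.0, 75.0))
times = [16.0, 28.0, 40.0, 52.0, 64.0, 76.0]

courses = {}
for condition, factor, seed in [("light", 1.0, 11), ("dark", 0.4, 12)]:
    profile = KineticProfile(c0=30.0, c_max=70.0, t_mid=40.0, rate=0.15,
                             light_factor=factor)
    data = rq.simulate_timecourse(profile, times, replicates=3,
                                  noise_sd=NOISE_SD_MID, seed=seed)
    courses[condition] = rq.quantify_timecourse(data, model, condition)

for condition, tc in courses.items():
    pretty = ", ".join(f"{t:.0f}h: {e.value:.1f}+-{e.sd:.1f}"
                       for t, e in zip(tc.times, tc.estimates))
    print(f"{condition:>5}: {pretty}")

cmp_ = rq.compare_conditions(courses["light"], courses["dark"])
print()
print(f"max production rate  light {cmp_['light']['max_rate']:.2f} "
      f"vs dark {cmp_['dark']['max_rate']:.2f} mmol/L/h "
      f"(ratio {cmp_['rate_ratio_light_over_dark']:.2f})")
print(f"midpoint crossing    light {cmp_['light']['midpoint_time']:.1f} h "
      f"vs dark {cmp_['dark']['midpoint_time']:.1f} h")
print()
print("Dark cultivation shows the same rising trend but a slower maximum")
print("rate and a later midpoint crossing - the prolonged synthesis cycle.")
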