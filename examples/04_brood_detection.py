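"""Detect brood rearing from comb telemetry and recover the ground truth.

A brood day needs the warmest sensor at >= 32 degC with daily amplitude
<= 2 degC; onset needs three consecutive brood days; an unrecovered drop
to <= 17 degC marks colony death.
"""

from phenobee.detect import analyze_colony
from phenobee.scenario import (
    EXPERIMENT_START,
    build_weekly_means,
    expand_hourly,
    sinusoidal_climatology,
)
from phenobee.synthetic import BroodPlan, SimulationConfig, simulate_colony_telemetry

profile = expand_hourly(
    build_weekly_means(sinusoidal_climatology()), EXPERIMENT_START, n_weeks=16
)
plan = BroodPlan("demo", episodes=((30, 25),), death_day=90)
config = SimulationConfig(seed=5, sensor_noise_sd=0.2)

telemetry = simulate_colony_telemetry(config, profile, plan)
result = analyze_colony(telemetry)


def day(ts):
    return None if ts is None else (ts.date() - EXPERIMENT_START).days + 1


print(f"plan:     onset day {plan.episodes[0][0]}, 25-day episode, death day {plan.death_day}")
print(f"detected: onset day {day(result['onset'])}, death day {day(result['death'])}")
print(f"brood days {result['n_brood_days']} of {result['n_days']} observed "
      f"(fraction {result['brood_fraction']:.3f}; days after death excluded)")
print("With 0.2 degC sensor noise and 0.5 degC logger quantization the "
      "detector still lands within a day of the generating plan.")
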