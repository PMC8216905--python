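"""Build the current and +4 degC chamber temperature programs.

Averages a daily climatology into 52 calendar weeks (week 52 spans the
last nine days), applies the warming offset, and expands to hourly
setpoints with the triangular +-3 degC daily cycle.
"""

from phenobee.scenario import (
    EXPERIMENT_START,
    apply_warming_offset,
    build_weekly_means,
    expand_hourly,
    sinusoidal_climatology,
)

clim = sinusoidal_climatology()  # Wuerzburg-like stand-in; any CSV works
current = build_weekly_means(clim)
future = apply_warming_offset(current, 4.0)

print(f"week  1 mean: current {current.weekly_mean[0]:6.2f} degC, "
      f"future {future.weekly_mean[0]:6.2f} degC")
print(f"week 52 mean: current {current.weekly_mean[51]:6.2f} degC "
      "(averaged over the year's last nine days)")

profile = expand_hourly(current, EXPERIMENT_START, n_weeks=2)
day1 = profile.table.iloc[:24]
print("\nfirst experiment day (2017-11-14), hourly setpoints:")
print("  00:00 {:5.2f}  06:00 {:5.2f}  12:00 {:5.2f}  18:00 {:5.2f} degC".format(
    *day1["setpoint_c"].iloc[[0, 6, 12, 18]]
))
print(f"  daily mean {day1['setpoint_c'].mean():.2f} degC "
      "= the governing weekly mean; min at midnight, max at noon, 0.5 degC steps")
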