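"""Operating-mode power budget and duty-cycled recording arithmetic.

Reproduces the device's mode catalog (power at the 1.8 V rail,
lifetime on a 240 mAh coin cell) and shows how a duty-cycled schedule
trades data for endurance.
"""

import biologger as bl

table = bl.reproduce_mode_table()
print(table[["name", "current_ma", "power_display", "power_unit",
             "lifetime_display", "quoted_lifetime"]].to_string(index=False))

# A 20% duty cycle: record 1 min of every 5 min.
schedule = bl.RecordingSchedule(on_s=60, period_s=300)
duty, avg = bl.schedule_stats(schedule, i_on_ma=2.3, i_off_ma=0.025)
est = bl.lifetime_days(bl.Battery(), avg)
print(f"\n20% duty cycle: average draw {avg:.3f} mA -> "
      f"{est.power_mw:.2f} mW, {est.lifetime_days:g} days")
# Duty cycling stretches a ~4-day continuous budget toward three weeks.
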