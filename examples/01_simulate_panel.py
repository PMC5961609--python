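"""Generate a small synthetic winter logger panel and look at its structure.

Builds 12 dwellings monitored in three rooms over February 2011 at 20-minute
cadence, with the default between-home spread (SD 2.5 °C), heating schedule,
absence excursions and missing days, then prints the panel dimensions and
the spread of per-dwelling winter means.
"""

import numpy as np

from coldhomes.synthetic import SimConfig, generate_households, generate_series

cfg = SimConfig(n_dwellings=12, months=((2011, 2),), seed=42)
households = generate_households(cfg)
series = generate_series(households, cfg)

print(f"households: {len(households)}  (LTD: {households['ltd'].sum()}, "
      f"over-64: {households['over64'].sum()})")
print(f"series: {len(series)} dwelling×room records")
s = series[0]
print(f"first series: {s.dwelling_id}/{s.room}, {len(s)} readings "
      f"({len(s) // 72} full days at 72 readings/day)")

means = np.array([x.temps.mean() for x in series if x.room == "living_room"])
print(f"living-room winter means: {means.min():.1f}–{means.max():.1f} °C "
      f"(SD {means.std(ddof=1):.2f} °C)")
# The SD across homes is what makes the 18 °C recommendation bite: even when
# the average home is warm enough, a sizeable share of homes is not.
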