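"""Detect activity onsets from a synthetic nest-temperature trace.

Programs three mornings of off-bouts into a 3-minute logger trace
(0.5 degC quantisation), then recovers the first-departure times with
the threshold-based bout detector and compares them to the programmed
truth.
"""

import datetime as dt

import numpy as np

from chronest import SimulationConfig, gen_ambient_trace, gen_nest_temperature
from chronest.bout_detect import april_day, detect_onsets_for_trace

cfg = SimulationConfig(seed=4, logger_accuracy=0.5)
ambient = gen_ambient_trace(5, seed=4, start=dt.date(2021, 4, 10))

rng = np.random.default_rng(4)
schedule, programmed = {}, {}
for d in range(1, 4):
    date = dt.date(2021, 4, 10 + d)
    onset = float(rng.uniform(5.0, 6.2))  # hours after midnight
    schedule[date] = [(onset, 12.0), (onset + 2.5, 15.0), (12.0, 20.0)]
    programmed[april_day(date)] = onset

trace = gen_nest_temperature(schedule, ambient, cfg,
                             incubation_start=dt.date(2021, 4, 11))
brood = {"female_id": "F0001", "brood_id": "B1", "nest_box": "N1",
         "year": 2021, "incubation_start": 8}
onsets, qc = detect_onsets_for_trace(trace, brood)

print("April day | programmed | detected | error (min)")
for row in onsets.itertuples():
    t = programmed[row.date]
    print(f"{row.date:9d} | {t:10.3f} | {row.onset:8.3f} | {abs(row.onset - t) * 60:.1f}")
print("\nEach detected onset is the start of the first off-bout after the")
print("nocturnal sit; errors stay within one 3-minute sampling interval.")
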