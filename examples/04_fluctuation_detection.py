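"""Detect localization-resets in N/C traces and summarize a cohort.

A fluctuation is a continuous monotone change of at least 0.12 N/C units;
continuity breaks when the trace moves less than 0.005 over any 3-frame
window.  A "reset" (fast nuclear exodus then re-entry) therefore appears as
a decrease event followed by an increase event.
"""

import numpy as np

from locreset import fluctuations as fl
from locreset.synthetic import NCEvent, nc_series

rng = np.random.default_rng(0)

# cohort of 50 cells, 20 of them programmed with one localization-reset
events, track_ids = [], []
for tid in range(50):
    program = (NCEvent(onset=15, kind="reset", amplitude=0.4, duration=10),) \
        if tid < 20 else ()
    trace = nc_series(1.8, program, 60) + rng.normal(0, 0.01, 60)
    track_ids.append(tid)
    events.extend(fl.detect(trace, track_id=tid))

stats = fl.cohort_stats(events, track_ids, observation_span=24.0)  # hours
print(f"events detected: {stats.n_events}")
print(f"fraction of cells fluctuating: {stats.fraction:.2f} (programmed 0.40)")
print(f"mean frequency: {stats.frequencies.mean():.3f} events/h")
print(f"median amplitude: {np.median(stats.amplitudes):.3f} N/C units "
      f"(programmed dip 0.4)")
# Each programmed reset yields a decrease and an increase event; unprogrammed
# cells should contribute (almost) none at this noise level.
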