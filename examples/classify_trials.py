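"""Apply the validity and response rules to hand-built trajectories.

Four trials of one larva: a clear rightward response, a response against
the stripes, a stationary trial, and a trial starting too close to the lane
end (invalid — not enough room to respond).
"""

import numpy as np

from omr_assay import ArenaGeometry, response_rate
from omr_assay.response import make_trial_record
from omr_assay.tracking import Trajectory


def traj(positions):
    pos = np.asarray(positions, dtype=float)
    return Trajectory(0, pos, np.full(len(pos), 60.0), np.ones(len(pos), bool))


geometry = ArenaGeometry()  # 135 mm lanes -> 27 mm threshold
fps = 20.0
scenarios = [
    ("follows stripes 40 mm right", np.linspace(60, 100, 200), +1),
    ("swims 40 mm against leftward stripes", np.linspace(60, 100, 200), -1),
    ("stays put", np.full(200, 60.0), +1),
    ("starts 10 mm from the left end, stripes leftward", np.full(200, 10.0), -1),
]

records = []
for i, (label, pos, direction) in enumerate(scenarios, start=1):
    rec = make_trial_record(traj(pos), i, direction, geometry, fps)
    records.append(rec)
    print(
        f"trial {i} ({label}): valid={rec.valid} responsive={rec.responsive} "
        f"displacement={rec.max_signed_displacement_mm:+.1f} mm"
    )

result = response_rate(records)
print(
    f"\nlarva: {result.n_responses} responses / {result.n_valid} valid trials "
    f"-> rate {result.response_rate_pct:.1f}% (included={result.included})"
)
# 3 valid trials (the short-start trial is discarded), 1 response -> 33.3%.
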