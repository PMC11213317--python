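"""Render the standard moving-stripe protocol from physical units.

Builds an 8 mm black/white stripe pattern moving at 6.5 mm/s — the
workhorse condition of the assay — converts it to display units
(0.2 mm/px, 50 fps) and renders the 30 s protocol.
"""

import numpy as np

from omr_assay import StimulusConfig, default_schedule, iter_sequence
from omr_assay.stimulus import mm_per_s_to_px_per_frame, stripe_width_mm_to_px

base = StimulusConfig(canvas_width_px=320, canvas_height_px=40)
config = StimulusConfig(
    stripe_width_px=stripe_width_mm_to_px(8.0, base),       # 8 mm -> 40 px
    speed_px_per_frame=mm_per_s_to_px_per_frame(6.5, base),  # 6.5 mm/s -> 0.65 px/frame
    canvas_width_px=320,
    canvas_height_px=40,
)
print(f"stripe width: {config.stripe_width_px} px "
      f"(pattern period {config.period_px} px)")
print(f"speed: {config.speed_px_per_frame:g} px/frame at {config.display_fps:g} fps")

n = 0
last = None
for frame in iter_sequence(config, default_schedule()):
    n += 1
    last = frame
print(f"protocol: {n} frames over {default_schedule().total_duration_s:g} s")
print(f"offset at the last frame: {last.accumulated_offset_px:g} px "
      "(one step short of cancelling the rightward excursion)")
# The 1500 frames cover 5 s still / 10 s right / 5 s still / 10 s left;
# the last frame sits one 0.65 px step before the motion fully cancels.
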