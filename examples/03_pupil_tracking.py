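"""Track a synthetic pupil through camera jitter and drift.

Frames contain a dark pupil disk and a bright corneal reflection (CR).
The CR moves with the camera, so referencing pupil position to the CR
cancels the jitter; slow drift is removed by the 1000-point Gaussian
high-pass, and positions are reported in % of the eye width.
"""

import numpy as np

from splinelnp.eye_tracking import EyeAxes, build_eye_timeseries, track_frames
from splinelnp.simulate import simulate_eye_frames

rng = np.random.default_rng(0)
n = 1500
true_x = 80 + 10 * np.sin(2 * np.pi * np.arange(n) / 200)
centers = np.column_stack([true_x, np.full(n, 60.0)])
jitter = np.column_stack([
    3 * np.sin(2 * np.pi * np.arange(n) / 37),
    2 * np.cos(2 * np.pi * np.arange(n) / 53),
])

frames, truth = simulate_eye_frames(centers, camera_jitter=jitter)
results = track_frames(frames, pupil_threshold=90, cr_threshold=200)
print(f"valid frames           : {sum(r.valid for r in results)}/{n}")

axes = EyeAxes((20.0, 60.0), (140.0, 60.0))  # tear duct -> outer canthus
e_h, e_v, keep = build_eye_timeseries(results, axes)

true_pct = (true_x - true_x.mean()) / axes.eye_width * 100
r = np.corrcoef(e_h[keep], true_pct[keep])[0, 1]
print(f"eye width              : {axes.eye_width:.0f} px")
print(f"corr(E_h, truth)       : {r:.3f}")
print(f"E_h range              : {e_h.min():.2f} to {e_h.max():.2f} "
      "% eye width")
# Despite several pixels of camera jitter, the CR reference recovers
# the commanded oscillation nearly perfectly in normalized units.
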