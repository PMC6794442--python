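"""Render the simulated stereo environment and inspect retinal projections.

Builds the default scene (fixated midline boundary plus a depth-varying
target strip 0.3 deg into the left visual field), renders it at several
disparities, and prints where the target's contrast edge lands on each
retina.  Positive disparity (farther than the horopter) displaces the
contralateral (left-eye) projection eccentrically and the ipsilateral
projection foveally; at zero disparity the two retinal images are
identical.
"""

import numpy as np

from stereoevo import SceneSpec, anticorrelate, render_stereo

BG = 1.0

for disparity in (0.0, 0.04, 0.12, -0.12):
    pair = render_stereo(SceneSpec(target_disparity=disparity))
    left_edge = int(np.argmax(pair.left_profile > BG))
    right_edge = int(np.argmax(pair.right_profile > BG))
    same = np.array_equal(pair.left_profile, pair.right_profile)
    print(
        f"disparity {disparity:+.2f} deg: target edge at column {left_edge} (contra) "
        f"/ {right_edge} (ipsi); images identical: {same}"
    )

pair = render_stereo(SceneSpec(target_disparity=0.06))
anti = anticorrelate(pair, "contralateral")
print(
    "\nanti-correlated pair: left-eye figure luminance "
    f"{pair.left_profile.max():.0f} -> {anti.left_profile[pair.left_profile == 400.0][0]:.0f} cd/m^2, "
    f"labels preserved (disparity {anti.target_disparity:+.2f} deg)"
)
print(
    "Each column is one 0.01-deg sensor pixel; a 0.04-deg disparity moves "
    "each eye's edge by 2 pixels in opposite directions."
)
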