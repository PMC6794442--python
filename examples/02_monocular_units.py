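"""Probe the fixed monocular front end.

Places the anatomically corresponding unit pairs (fixation at 0 deg, target
at -0.3 deg) and prints each unit's activity as the target surface moves in
depth.  The contralateral unit's activity grows with far disparity while
the ipsilateral unit's shrinks — this activity difference at anatomically
corresponding positions is the disparity signal everything downstream
evolves to read.
"""

import numpy as np

from stereoevo import SceneSpec, place_monocular_pairs, render_stereo

assembly = place_monocular_pairs(stage="absolute")
print(f"unit receptive field span: {assembly.units[0].span_deg:.2f} deg")
print(f"{'disparity':>10} {'contra@target':>14} {'ipsi@target':>12} {'difference':>11}")
for disparity in np.arange(-0.18, 0.18 + 1e-9, 0.06):
    pair = render_stereo(SceneSpec(target_disparity=float(disparity)))
    acts = assembly.activities(pair)
    print(
        f"{disparity:>+10.2f} {acts[2]:>14.4f} {acts[3]:>12.4f} {acts[2] - acts[3]:>+11.4f}"
    )
print(
    "\nA positive contra-minus-ipsi difference marks surfaces farther than "
    "the horopter, a negative one nearer surfaces; the magnitude grows with "
    "|disparity| until the edge leaves the 0.12-deg ON centre."
)
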