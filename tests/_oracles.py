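"""Independent scalar reference implementations used as test oracles.

Everything here is deliberately written with plain Python loops and
``math.exp`` so it shares no code path with the vectorised package
implementations it checks.
"""

import math


def oracle_sigmoid(pre, gain, slope, offset, sign):
    return sign * gain / (1.0 + math.exp(-slope * pre + offset))


def oracle_eye_profile(scene, geometry, eye):
    """Per-column luminances for one eye, integrating strip coverage per pixel."""
    half = -0.5 if eye == "contralateral" else 0.5
    strips = [(scene.fixation_azimuth, scene.fixation_azimuth + scene.fixation_width)]
    edge = scene.target_offset + half * scene.target_disparity
    strips.append((edge, edge + scene.strip_width))
    if scene.reference_offset is not None:
        redge = scene.reference_offset + half * scene.reference_disparity
        strips.append((redge, redge + scene.strip_width))
    profile = []
    for col in range(geometry.width_px):
        # integrate strip-union coverage of this column by fine sampling
        a = (col - geometry.width_px / 2.0) * geometry.pixel_deg
        n_sub = 400
        covered = 0
        for k in range(n_sub):
            az = a + (k + 0.5) / n_sub * geometry.pixel_deg
            if any(lo <= az <= hi for lo, hi in strips):
                covered += 1
        frac = covered / n_sub
        profile.append(
            scene.background_luminance
            + (scene.figure_luminance - scene.background_luminance) * frac
        )
    return profile


def oracle_monocular(image, unit):
    """Scalar per-pixel evaluation of one monocular unit on a 2-D image."""
    total = 0.0
    r0, c0 = unit.row_start, unit.col_start
    for idx, params in enumerate(unit.subregion_params):
        br = r0 + (idx // 3) * 12
        bc = c0 + (idx % 3) * 12
        acc = 0.0
        for r in range(br, br + 12):
            for c in range(bc, bc + 12):
                acc += image[r][c]
        drive = acc / 144.0 / unit.figure_luminance
        total += oracle_sigmoid(drive, params.gain, params.slope, params.offset, params.sign)
    out = unit.output_params
    return oracle_sigmoid(total, out.gain, out.slope, out.offset, out.sign)


def oracle_binocular(inputs, genome):
    """Scalar sum-of-sigmoids forward pass (second or third order)."""
    total = 0.0
    for pre, conn in zip(inputs, genome.connections):
        total += oracle_sigmoid(pre, conn.gain, conn.slope, conn.offset, conn.sign)
    return total
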