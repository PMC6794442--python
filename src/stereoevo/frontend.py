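"""Fixed monocular front end: ON-centre / eight-OFF-subregion units.

Each monocular unit has a 36 x 36-pixel receptive field (0.36 deg of visual
angle) tiled exactly by a 3 x 3 grid of 12 x 12-pixel subregions: the centre
block is ON, the eight surround blocks OFF.  The average luminance of each
block, normalised by the figure luminance, drives a preset signed logistic;
a final preset sigmoid (gain 0.9771, slope 5.7152, offset 1.7300) compiles
the sum of the nine subregion outputs into the unit's scalar activity.

None of these parameters evolve.  The surround gain defaults to 1/8 of the
centre gain so that the eight OFF blocks exactly balance the ON centre: a
uniform field produces zero net drive, the classic balanced centre-surround
arrangement, which leaves the unit responsive to contrast edges rather than
mean luminance.

Units come in anatomically corresponding pairs — one unit per eye at
*identical array coordinates* — spaced 0.3 deg apart: a pair under the
fixated edge at azimuth 0, a pair at the target azimuth (-0.3 deg), and for
the relative-disparity stage a third pair at the reference azimuth
(-0.6 deg).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geometry import DEFAULT_GEOMETRY, SensorGeometry
from .sigmoid import SigmoidParams, logistic
from .stimuli import FIGURE_LUMINANCE, StereoPair, StimulusBank

FIELD_PX = 36
BLOCK_PX = 12

OUTPUT_SIGMOID = SigmoidParams(gain=0.9771, slope=5.7152, offset=1.7300, sign=1)
CENTER_SIGMOID = SigmoidParams(gain=1.0, slope=6.0, offset=1.5, sign=1)
SURROUND_SIGMOID = SigmoidParams(gain=0.125, slope=6.0, offset=1.5, sign=-1)

ABSOLUTE_POSITIONS = (0.0, -0.3)
RELATIVE_POSITIONS = (0.0, -0.3, -0.6)


def default_subregion_params(
    center: SigmoidParams = CENTER_SIGMOID,
    surround: SigmoidParams = SURROUND_SIGMOID,
) -> tuple:
    """Nine subregion sigmoids in row-major grid order (index 4 = ON centre)."""
    params = [surround] * 9
    params[4] = center
    return tuple(params)


@dataclass(frozen=True)
class MonocularUnit:
    """One fixed centre-surround monocular unit."""

    center_azimuth: float
    geometry: SensorGeometry = DEFAULT_GEOMETRY
    subregion_params: tuple = field(default_factory=default_subregion_params)
    output_params: SigmoidParams = OUTPUT_SIGMOID
    figure_luminance: float = FIGURE_LUMINANCE
    center_row: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.subregion_params) != 9:
            raise ValueError("a unit has exactly nine subregion sigmoids")
        if not (0 <= self.col_start and self.col_start + FIELD_PX <= self.geometry.width_px):
            raise ValueError(
                f"receptive field at azimuth {self.center_azimuth} falls outside the array"
            )
        if not (0 <= self.row_start and self.row_start + FIELD_PX <= self.geometry.height_px):
            raise ValueError("receptive field exceeds the array vertically")

    @property
    def span_deg(self) -> float:
        """Angular extent of the full receptive field."""
        return FIELD_PX * self.geometry.pixel_deg

    @property
    def col_start(self) -> int:
        x = self.geometry.x_from_azimuth(self.center_azimuth)
        return int(round(x)) - FIELD_PX // 2

    @property
    def row_start(self) -> int:
        if self.center_row is not None:
            return int(self.center_row) - FIELD_PX // 2
        return (self.geometry.height_px - FIELD_PX) // 2

    def blocks(self) -> list:
        """(row0, col0) of each 12 x 12 subregion, row-major."""
        return [
            (self.row_start + r * BLOCK_PX, self.col_start + c * BLOCK_PX)
            for r in range(3)
            for c in range(3)
        ]


def subregion_drive(image: np.ndarray, block: tuple, figure_luminance: float = FIGURE_LUMINANCE) -> float:
    """Normalised mean luminance of one subregion block.

    ``block`` is (row0, col0, height, width).  The mean is divided by the
    figure luminance so drives lie in [0, 1] for in-range images.
    """
    r0, c0, h, w = block
    if r0 < 0 or c0 < 0 or r0 + h > image.shape[0] or c0 + w > image.shape[1]:
        raise ValueError("subregion block out of image bounds")
    return float(np.mean(image[r0 : r0 + h, c0 : c0 + w])) / figure_luminance


def monocular_response(image: np.ndarray, unit: MonocularUnit) -> float:
    """Activity of one monocular unit on one eye's image.

    The nine subregion drives pass through their preset sigmoids, the results
    are summed, and the sum passes through the preset output sigmoid.
    Deterministic and bounded in [0, output gain].
    """
    if image.shape != (unit.geometry.height_px, unit.geometry.width_px):
        raise ValueError("image shape does not match the unit's sensor geometry")
    total = 0.0
    for params, (r0, c0) in zip(unit.subregion_params, unit.blocks()):
        drive = subregion_drive(image, (r0, c0, BLOCK_PX, BLOCK_PX), unit.figure_luminance)
        total += logistic(drive, params)
    return logistic(total, unit.output_params)


def profile_responses(profiles: np.ndarray, unit: MonocularUnit) -> np.ndarray:
    """Vectorised unit activities for a stack of luminance profiles.

    ``profiles`` has shape (n, width_px); each row is a vertically uniform
    image, for which the subregion block mean equals the mean over the
    block's 12 columns.  Bit-equivalent to :func:`monocular_response` on the
    broadcast images.
    """
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    if profiles.shape[1] != unit.geometry.width_px:
        raise ValueError("profile length must equal sensor width")
    c0 = unit.col_start
    bands = np.stack(
        [
            profiles[:, c0 + i * BLOCK_PX : c0 + (i + 1) * BLOCK_PX].mean(axis=1)
            for i in range(3)
        ],
        axis=1,
    )  # (n, 3) column-band drives
    drives = bands / unit.figure_luminance
    total = np.zeros(profiles.shape[0])
    for idx, params in enumerate(unit.subregion_params):
        total += logistic(drives[:, idx % 3], params)
    return logistic(total, unit.output_params)


@dataclass(frozen=True)
class MonocularAssembly:
    """Anatomically corresponding monocular pairs at fixed azimuths.

    Within each pair the contralateral (left-eye) and ipsilateral (right-eye)
    units occupy identical array coordinates; pairs are spaced 0.3 deg apart.
    Activity columns are ordered (contra, ipsi) per position, positions in
    the order given (fixation, target[, reference]).
    """

    positions: tuple
    geometry: SensorGeometry = DEFAULT_GEOMETRY
    units: tuple = ()

    def __post_init__(self) -> None:
        if not self.units:
            object.__setattr__(
                self,
                "units",
                tuple(MonocularUnit(center_azimuth=p, geometry=self.geometry) for p in self.positions),
            )
        if len(self.units) != len(self.positions):
            raise ValueError("one unit template per position")

    @property
    def n_pairs(self) -> int:
        return len(self.positions)

    @property
    def stage(self) -> str:
        return "relative" if self.n_pairs == 3 else "absolute"

    def column_names(self) -> list:
        names = []
        tags = ["fixation", "target", "reference"]
        for tag, _ in zip(tags, self.positions):
            names.extend([f"contra@{tag}", f"ipsi@{tag}"])
        return names

    def activities(self, pair: StereoPair) -> np.ndarray:
        """(2 * n_pairs,) activities for one stereo pair."""
        return self.bank_activities([pair])[0]

    def bank_activities(self, bank) -> np.ndarray:
        """(n, 2 * n_pairs) activities for a bank or sequence of pairs.

        The contralateral column of each pair comes from the left-eye
        profile, the ipsilateral column from the right-eye profile.  Shared
        across all individuals of an evolving population (the front end is
        fixed).
        """
        pairs: Sequence[StereoPair] = bank.pairs if isinstance(bank, StimulusBank) else bank
        left = np.stack([p.left_profile for p in pairs])
        right = np.stack([p.right_profile for p in pairs])
        cols = []
        for unit in self.units:
            cols.append(profile_responses(left, unit))
            cols.append(profile_responses(right, unit))
        return np.stack(cols, axis=1)


def place_monocular_pairs(
    geometry: SensorGeometry = DEFAULT_GEOMETRY,
    stage: str = "absolute",
    **unit_kwargs,
) -> MonocularAssembly:
    """Build the standard assembly for a stage.

    "absolute": pairs at 0.0 and -0.3 deg (fixation, target).
    "relative": adds the reference pair at -0.6 deg.
    """
    if stage == "absolute":
        positions = ABSOLUTE_POSITIONS
    elif stage == "relative":
        positions = RELATIVE_POSITIONS
    else:
        raise ValueError(f"stage must be 'absolute' or 'relative', got {stage!r}")
    units = tuple(
        MonocularUnit(center_azimuth=p, geometry=geometry, **unit_kwargs) for p in positions
    )
    return MonocularAssembly(positions=positions, geometry=geometry, units=units)


def third_order_field_extent(assembly: MonocularAssembly) -> float:
    """Pooled receptive-field extent of the relative-disparity stage.

    Union of the target- and reference-position monocular fields (the
    positions whose activity differences carry the relative-disparity
    signal), in degrees.
    """
    if assembly.stage != "relative":
        raise ValueError("pooled extent is defined for the relative stage")
    spans = []
    for unit in assembly.units[1:]:
        half = unit.span_deg / 2.0
        spans.append((unit.center_azimuth - half, unit.center_azimuth + half))
    lo = min(s[0] for s in spans)
    hi = max(s[1] for s in spans)
    return hi - lo
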