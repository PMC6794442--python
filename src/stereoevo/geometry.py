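"""Geometry of the paired sensor arrays (the model "retinas").

Each eye is a pinhole camera projecting the scene onto a dense rectangular
array of luminance sensors.  Azimuth is measured in signed degrees of visual
angle, negative to the left of the midline; the array is centred on the
midline, so the default 200-column array at 0.01 deg/pixel spans [-1, +1] deg.
Pixel indexing is 0-based with row 0 at the top and column 0 at the left.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class SensorGeometry:
    """Shape and angular scale of one eye's sensor array.

    Parameters
    ----------
    width_px, height_px
        Array size in pixels (columns, rows).
    pixel_deg
        Degrees of visual angle per pixel (square pixels).
    """

    width_px: int = 200
    height_px: int = 40
    pixel_deg: float = 0.01

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("sensor dimensions must be strictly positive")
        if self.pixel_deg <= 0:
            raise ValueError("pixel_deg must be strictly positive")

    @property
    def horizontal_span(self) -> float:
        """Total horizontal extent in degrees (width_px * pixel_deg)."""
        return self.width_px * self.pixel_deg

    @property
    def vertical_span(self) -> float:
        """Total vertical extent in degrees (height_px * pixel_deg)."""
        return self.height_px * self.pixel_deg

    @property
    def azimuth_min(self) -> float:
        return -self.horizontal_span / 2.0

    @property
    def azimuth_max(self) -> float:
        return self.horizontal_span / 2.0

    def x_from_azimuth(self, azimuth: float) -> float:
        """Continuous column coordinate of an azimuth.

        Column ``c`` covers the half-open interval ``[c, c + 1)`` in this
        coordinate, so azimuth_min maps to 0.0 and azimuth_max to width_px.
        """
        return azimuth / self.pixel_deg + self.width_px / 2.0

    def column_center_azimuth(self, col: int) -> float:
        """Azimuth of the centre of column ``col``."""
        return (col + 0.5 - self.width_px / 2.0) * self.pixel_deg


DEFAULT_GEOMETRY = SensorGeometry()
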