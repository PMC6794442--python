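"""Simulated stereo environment: luminous strips projected onto paired retinas.

The world holds up to three fronto-parallel luminous strips (400 cd/m^2 on a
1 cd/m^2 background) seen through pinholes by two sensor arrays:

* a fixation strip on the horopter, its fixated edge at the midline
  (azimuth 0), identical in both eyes;
* a target strip whose defining vertical contrast edge sits at the target
  azimuth (default -0.3 deg, left visual field) and whose depth relative to
  the horopter is expressed directly as a signed disparity in degrees
  (positive = farther / uncrossed, negative = nearer / crossed);
* optionally a reference strip (default -0.6 deg) for the relative-disparity
  stage.

A disparity ``d`` displaces the strip's edge by ``-d/2`` in the contralateral
eye and ``+d/2`` in the ipsilateral eye: for a far target the contralateral
projection moves eccentrically (leftward for a left-field target) and the
ipsilateral projection foveally, and the displacements exchange for near
targets.  The target lies in the left visual field, so the left eye is
labelled *contralateral* and the right eye *ipsilateral* (right-hemisphere
convention); code should address eyes through these labels.

Strips extend foveally (rightward) from their defining edge, so the edge at
the strip's eccentric side is the one centred on the corresponding monocular
receptive field.  Sub-pixel edge positions are rendered by area-weighted
anti-aliasing of the edge column, making disparity continuous despite the
0.01 deg pixel grid.  All scenes are uniform along the vertical axis, so
images are stored internally as single luminance rows ("profiles") and
broadcast to full arrays on demand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import DEFAULT_GEOMETRY, SensorGeometry

MAX_DISPARITY = 0.18  # degrees; half the 0.36 deg monocular receptive field
FIGURE_LUMINANCE = 400.0  # cd/m^2
BACKGROUND_LUMINANCE = 1.0  # cd/m^2

EYE_LABELS = ("contralateral", "ipsilateral")
BANK_KINDS = ("absolute_far", "absolute_near", "relative", "control")


@dataclass(frozen=True)
class SceneSpec:
    """One configuration of the simulated environment.

    Disparities are signed degrees of visual angle (positive = uncrossed /
    farther than the horopter).  ``reference_offset``/``reference_disparity``
    are both present (relative-disparity stage) or both absent.
    """

    target_offset: float = -0.3
    target_disparity: float = 0.0
    reference_offset: Optional[float] = None
    reference_disparity: Optional[float] = None
    fixation_azimuth: float = 0.0
    fixation_width: float = 0.3
    strip_width: float = 0.15
    figure_luminance: float = FIGURE_LUMINANCE
    background_luminance: float = BACKGROUND_LUMINANCE

    def __post_init__(self) -> None:
        if abs(self.target_disparity) > MAX_DISPARITY + 1e-12:
            raise ValueError(
                f"|target_disparity| must be <= {MAX_DISPARITY} deg, "
                f"got {self.target_disparity}"
            )
        if (self.reference_offset is None) != (self.reference_disparity is None):
            raise ValueError("reference_offset and reference_disparity go together")
        if self.reference_disparity is not None and abs(self.reference_disparity) > MAX_DISPARITY + 1e-12:
            raise ValueError("|reference_disparity| out of range")
        if self.figure_luminance <= self.background_luminance:
            raise ValueError("figure_luminance must exceed background_luminance")
        if self.background_luminance < 0:
            raise ValueError("luminances must be non-negative")
        if self.strip_width <= 0 or self.fixation_width <= 0:
            raise ValueError("strip widths must be positive")

    @property
    def has_reference(self) -> bool:
        return self.reference_offset is not None

    @property
    def relative_disparity(self) -> Optional[float]:
        if not self.has_reference:
            return None
        return self.target_disparity - self.reference_disparity


@dataclass(frozen=True)
class StereoPair:
    """Paired left/right luminance images with ground-truth disparities.

    ``left_profile``/``right_profile`` are single luminance rows (cd/m^2);
    full images are vertical broadcasts of the profiles (every scene is
    uniform along the vertical axis).  The contralateral label maps to the
    left eye for the left-visual-field target.
    """

    left_profile: np.ndarray
    right_profile: np.ndarray
    geometry: SensorGeometry
    target_disparity: float
    reference_disparity: Optional[float] = None
    figure_luminance: float = FIGURE_LUMINANCE
    background_luminance: float = BACKGROUND_LUMINANCE

    eye_labels = {"contralateral": "left", "ipsilateral": "right"}

    def __post_init__(self) -> None:
        if self.left_profile.shape != self.right_profile.shape:
            raise ValueError("eye profiles must have identical shape")
        if self.left_profile.shape != (self.geometry.width_px,):
            raise ValueError("profile length must equal sensor width")

    @property
    def relative_disparity(self) -> Optional[float]:
        if self.reference_disparity is None:
            return None
        return self.target_disparity - self.reference_disparity

    def profile(self, eye: str) -> np.ndarray:
        """Luminance row for an eye addressed by anatomical label."""
        side = self.eye_labels.get(eye, eye)
        if side == "left":
            return self.left_profile
        if side == "right":
            return self.right_profile
        raise ValueError(f"unknown eye {eye!r}")

    def image(self, eye: str) -> np.ndarray:
        """Full (height_px, width_px) luminance image for an eye."""
        return np.tile(self.profile(eye), (self.geometry.height_px, 1))

    @property
    def left_image(self) -> np.ndarray:
        return self.image("left")

    @property
    def right_image(self) -> np.ndarray:
        return self.image("right")


def _merge_intervals(intervals: Sequence[tuple]) -> list:
    """Merge possibly-overlapping [a, b] azimuth intervals into a disjoint set."""
    merged: list = []
    for a, b in sorted(intervals):
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def _eye_intervals(scene: SceneSpec, eye: str) -> list:
    """Figure intervals (azimuth degrees) seen by one eye.

    The fixation strip lies on the horopter and is never displaced; the
    target (and reference) edge is displaced by -d/2 in the contralateral
    eye and +d/2 in the ipsilateral eye for signed disparity d.
    """
    if eye not in EYE_LABELS:
        raise ValueError(f"eye must be one of {EYE_LABELS}, got {eye!r}")
    half = -0.5 if eye == "contralateral" else 0.5
    intervals = [(scene.fixation_azimuth, scene.fixation_azimuth + scene.fixation_width)]
    edge = scene.target_offset + half * scene.target_disparity
    intervals.append((edge, edge + scene.strip_width))
    if scene.has_reference:
        redge = scene.reference_offset + half * scene.reference_disparity
        intervals.append((redge, redge + scene.strip_width))
    return _merge_intervals(intervals)


def _coverage_profile(intervals: Sequence[tuple], geometry: SensorGeometry) -> np.ndarray:
    """Per-column figure coverage in [0, 1] by area-weighted anti-aliasing."""
    cols = np.arange(geometry.width_px, dtype=float)
    cov = np.zeros(geometry.width_px)
    for a, b in intervals:
        xa = geometry.x_from_azimuth(a)
        xb = geometry.x_from_azimuth(b)
        cov += np.clip(np.minimum(xb, cols + 1.0) - np.maximum(xa, cols), 0.0, 1.0)
    return np.clip(cov, 0.0, 1.0)


def render_stereo(scene: SceneSpec, geometry: SensorGeometry = DEFAULT_GEOMETRY) -> StereoPair:
    """Project a scene through the two pinholes onto the sensor arrays.

    Deterministic; raises if any displaced strip edge falls outside the
    sensor span.
    """
    profiles = {}
    for eye in EYE_LABELS:
        intervals = _eye_intervals(scene, eye)
        for a, b in intervals:
            if a < geometry.azimuth_min - 1e-12 or b > geometry.azimuth_max + 1e-12:
                raise ValueError(
                    f"strip [{a:.4f}, {b:.4f}] deg falls outside the sensor span "
                    f"[{geometry.azimuth_min}, {geometry.azimuth_max}] in the {eye} eye"
                )
        cov = _coverage_profile(intervals, geometry)
        profiles[eye] = (
            scene.background_luminance
            + (scene.figure_luminance - scene.background_luminance) * cov
        )
    return StereoPair(
        left_profile=profiles["contralateral"],
        right_profile=profiles["ipsilateral"],
        geometry=geometry,
        target_disparity=scene.target_disparity,
        reference_disparity=scene.reference_disparity,
        figure_luminance=scene.figure_luminance,
        background_luminance=scene.background_luminance,
    )


def anticorrelate(pair: StereoPair, eye: str = "contralateral") -> StereoPair:
    """Contrast-reverse one eye's image (anti-correlated stereogram).

    Every figure pixel becomes background luminance and vice versa; columns
    carrying anti-aliased edge mixtures invert linearly about the mid-level.
    The other eye and all ground-truth labels are untouched.  Applying the
    operation twice to the same eye restores the original pair.
    """
    lo, hi = pair.background_luminance, pair.figure_luminance
    target = pair.profile(eye)
    if np.any(target < lo - 1e-9) or np.any(target > hi + 1e-9):
        raise ValueError(
            "anti-correlation requires a two-level (plus edge anti-aliasing) image"
        )
    flipped = (hi + lo) - target
    side = pair.eye_labels[eye]
    kwargs = {"left_profile": pair.left_profile, "right_profile": pair.right_profile}
    kwargs[f"{side}_profile"] = flipped
    return replace(pair, **kwargs)


# ---------------------------------------------------------------------------
# Stimulus banks


@dataclass
class StimulusBank:
    """An ordered, seeded collection of stereo pairs with ground-truth labels.

    ``labels`` hold the signed training disparity of each pair (absolute
    disparity for absolute/control banks, relative disparity target-minus-
    reference for relative banks).  Regeneration from (kind, params, seed)
    is bit-identical.
    """

    kind: str
    seed: int
    scenes: list
    pairs: list
    labels: np.ndarray
    params: dict = field(default_factory=dict)
    geometry: SensorGeometry = DEFAULT_GEOMETRY

    def __post_init__(self) -> None:
        if self.kind not in BANK_KINDS:
            raise ValueError(f"kind must be one of {BANK_KINDS}")
        if not (len(self.scenes) == len(self.pairs) == len(self.labels)):
            raise ValueError("scenes, pairs and labels must have equal length")

    def __len__(self) -> int:
        return len(self.pairs)


def _render_bank(kind, seed, scenes, labels, params, geometry) -> StimulusBank:
    pairs = [render_stereo(s, geometry) for s in scenes]
    return StimulusBank(
        kind=kind,
        seed=int(seed),
        scenes=scenes,
        pairs=pairs,
        labels=np.asarray(labels, dtype=float),
        params=params,
        geometry=geometry,
    )


def _disparity_magnitudes(rng, n, max_disparity):
    # uniform on the half-open interval (0, max_disparity]
    return max_disparity * (1.0 - rng.random(n))


def make_absolute_bank(
    n: int,
    polarity: str,
    max_disparity: float = MAX_DISPARITY,
    seed: int = 0,
    geometry: SensorGeometry = DEFAULT_GEOMETRY,
    scene: SceneSpec = SceneSpec(),
) -> StimulusBank:
    """Bank of single-target scenes of one depth polarity.

    Disparity magnitudes are drawn uniformly on ``(0, max_disparity]`` and
    signed by ``polarity`` ("far" = positive/uncrossed, "near" = negative/
    crossed); labels store the signed value.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < max_disparity <= MAX_DISPARITY:
        raise ValueError(f"max_disparity must be in (0, {MAX_DISPARITY}]")
    if polarity not in ("far", "near"):
        raise ValueError(f"polarity must be 'far' or 'near', got {polarity!r}")
    rng = np.random.default_rng(seed)
    disparities = _disparity_magnitudes(rng, n, max_disparity)
    if polarity == "near":
        disparities = -disparities
    scenes = [replace(scene, target_disparity=float(d), reference_offset=None,
                      reference_disparity=None) for d in disparities]
    params = {"n": n, "polarity": polarity, "max_disparity": max_disparity}
    return _render_bank(f"absolute_{polarity}", seed, scenes, disparities, params, geometry)


def make_relative_bank(
    n: int,
    max_disparity: float = MAX_DISPARITY,
    polarity: str = "rel_far",
    seed: int = 0,
    geometry: SensorGeometry = DEFAULT_GEOMETRY,
    scene: SceneSpec = SceneSpec(),
    reference_offset: float = -0.6,
) -> StimulusBank:
    """Bank of target+reference scenes with a fixed relative-disparity sign.

    Target and reference disparities are drawn independently and uniformly on
    ``[-max_disparity, +max_disparity]`` and rejection-sampled so the relative
    disparity (target - reference) has the sign required by ``polarity``
    ("rel_far" positive, "rel_near" negative).  All three depth-configuration
    classes — both strips far, straddling the horopter, both near — occur.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < max_disparity <= MAX_DISPARITY:
        raise ValueError(f"max_disparity must be in (0, {MAX_DISPARITY}]")
    if polarity not in ("rel_far", "rel_near"):
        raise ValueError(f"polarity must be 'rel_far' or 'rel_near', got {polarity!r}")
    rng = np.random.default_rng(seed)
    want = 1.0 if polarity == "rel_far" else -1.0
    targets, refs = [], []
    while len(targets) < n:
        k = max(2 * (n - len(targets)), 16)
        t = rng.uniform(-max_disparity, max_disparity, k)
        r = rng.uniform(-max_disparity, max_disparity, k)
        keep = np.sign(t - r) == want
        targets.extend(t[keep])
        refs.extend(r[keep])
    targets = np.asarray(targets[:n])
    refs = np.asarray(refs[:n])
    scenes = [
        replace(scene, target_disparity=float(t), reference_offset=reference_offset,
                reference_disparity=float(r))
        for t, r in zip(targets, refs)
    ]
    labels = targets - refs
    params = {
        "n": n,
        "polarity": polarity,
        "max_disparity": max_disparity,
        "reference_offset": reference_offset,
    }
    return _render_bank("relative", seed, scenes, labels, params, geometry)


def relative_class(target_disparity: float, reference_disparity: float) -> str:
    """Depth-configuration class of a relative-disparity scene."""
    if target_disparity > 0 and reference_disparity > 0:
        return "both_far"
    if target_disparity < 0 and reference_disparity < 0:
        return "both_near"
    return "straddle"


def control_offset_bounds(
    max_disparity: float = MAX_DISPARITY,
    strip_width: float = 0.15,
    margin: float = 0.18,
    geometry: SensorGeometry = DEFAULT_GEOMETRY,
) -> tuple:
    """Legal target-offset interval for the position-randomised control.

    Offsets are constrained so every rendered edge — either strip edge, after
    the largest possible +-max_disparity/2 displacement — stays at least
    ``margin`` degrees from the array borders.
    """
    lo = geometry.azimuth_min + margin + max_disparity / 2.0
    hi = geometry.azimuth_max - margin - strip_width - max_disparity / 2.0
    if lo >= hi:
        raise ValueError("no legal offsets under these constraints")
    return lo, hi


def make_control_bank(
    n: int,
    max_disparity: float = MAX_DISPARITY,
    seed: int = 0,
    polarity: str = "far",
    margin: float = 0.18,
    geometry: SensorGeometry = DEFAULT_GEOMETRY,
    scene: SceneSpec = SceneSpec(),
) -> StimulusBank:
    """Position-randomised control bank (retinotopy test).

    Like :func:`make_absolute_bank` but the target offset of every pair is
    drawn uniformly over the legal azimuth interval instead of being fixed at
    the trained retinotopic position; labels remain the absolute disparity.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < max_disparity <= MAX_DISPARITY:
        raise ValueError(f"max_disparity must be in (0, {MAX_DISPARITY}]")
    if polarity not in ("far", "near"):
        raise ValueError(f"polarity must be 'far' or 'near', got {polarity!r}")
    rng = np.random.default_rng(seed)
    disparities = _disparity_magnitudes(rng, n, max_disparity)
    if polarity == "near":
        disparities = -disparities
    lo, hi = control_offset_bounds(max_disparity, scene.strip_width, margin, geometry)
    offsets = rng.uniform(lo, hi, n)
    scenes = [
        replace(scene, target_offset=float(o), target_disparity=float(d),
                reference_offset=None, reference_disparity=None)
        for o, d in zip(offsets, disparities)
    ]
    params = {
        "n": n,
        "polarity": polarity,
        "max_disparity": max_disparity,
        "margin": margin,
    }
    return _render_bank("control", seed, scenes, disparities, params, geometry)


# ---------------------------------------------------------------------------
# Serialization: JSON manifest + CSV of scene/edge parameters (lightweight
# replay — pairs are re-rendered deterministically on load).

_SCENE_COLUMNS = [
    "target_offset",
    "target_disparity",
    "reference_offset",
    "reference_disparity",
    "fixation_azimuth",
    "fixation_width",
    "strip_width",
    "figure_luminance",
    "background_luminance",
]


def save_bank(bank: StimulusBank, path) -> None:
    """Write a bank as ``manifest.json`` + ``scenes.csv`` in a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "kind": bank.kind,
        "seed": bank.seed,
        "params": bank.params,
        "labels": [float(x) for x in bank.labels],
        "geometry": {
            "width_px": bank.geometry.width_px,
            "height_px": bank.geometry.height_px,
            "pixel_deg": bank.geometry.pixel_deg,
        },
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    rows = []
    for s in bank.scenes:
        rows.append({c: getattr(s, c) for c in _SCENE_COLUMNS})
    pd.DataFrame(rows, columns=_SCENE_COLUMNS).to_csv(path / "scenes.csv", index=False)


def load_bank(path) -> StimulusBank:
    """Re-render a bank saved by :func:`save_bank` (bit-identical)."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    geometry = SensorGeometry(**manifest["geometry"])
    frame = pd.read_csv(path / "scenes.csv", float_precision="round_trip")
    scenes = []
    for row in frame.itertuples(index=False):
        kwargs = dict(zip(_SCENE_COLUMNS, row))
        if pd.isna(kwargs["reference_offset"]):
            kwargs["reference_offset"] = None
            kwargs["reference_disparity"] = None
        scenes.append(SceneSpec(**kwargs))
    return _render_bank(
        manifest["kind"],
        manifest["seed"],
        scenes,
        np.asarray(manifest["labels"], dtype=float),
        manifest["params"],
        geometry,
    )
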