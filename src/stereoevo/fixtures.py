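"""Deterministic fixture generator: small banks and hand-built genomes.

Everything a test (or a quick interactive session) needs without any
download or long run: miniature stimulus banks of every kind, one
anti-correlated pair, and hand-constructed genomes with known probe
outcomes — a constant "perfect responder" paired with a constant-disparity
bank it solves exactly, a one-eyed unit (ODI +1), a mirror-symmetric unit
(ODI 0), and a zero-gain unit (all connections negligible).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .network import Genome, save_genomes
from .sigmoid import SigmoidParams
from .stimuli import (
    SceneSpec,
    StimulusBank,
    anticorrelate,
    make_absolute_bank,
    make_relative_bank,
    render_stereo,
    save_bank,
)


def constant_genome(level: float, stage: str = "second_order", polarity: str = "far") -> Genome:
    """A genome responding exactly ``level`` to every input.

    One zero-slope connection contributes gain/2 = level; the rest are
    zero-gain.
    """
    on = SigmoidParams(gain=2.0 * level, slope=0.0, offset=0.0, sign=1)
    off = SigmoidParams(gain=0.0, slope=0.0, offset=0.0, sign=1)
    return Genome(connections=(on, off, off, off), stage=stage, polarity=polarity)


def one_eyed_genome(eye: str = "contralateral") -> Genome:
    """Second-order genome driven exclusively by one eye (|ODI| = 1)."""
    live = SigmoidParams(gain=0.5, slope=8.0, offset=2.0, sign=1)
    dead = SigmoidParams(gain=0.0, slope=0.0, offset=0.0, sign=1)
    if eye == "contralateral":
        conns = (live, dead, live, dead)
    elif eye == "ipsilateral":
        conns = (dead, live, dead, live)
    else:
        raise ValueError(f"unknown eye {eye!r}")
    return Genome(connections=conns, stage="second_order", polarity="far")


def mirror_genome() -> Genome:
    """Second-order genome with identical contra/ipsi connections (ODI = 0)."""
    c = SigmoidParams(gain=0.3, slope=6.0, offset=1.0, sign=1)
    return Genome(connections=(c, c, c, c), stage="second_order", polarity="far")


def zero_gain_genome(stage: str = "second_order", polarity: str = "far") -> Genome:
    dead = SigmoidParams(gain=0.0, slope=1.0, offset=0.0, sign=1)
    return Genome(connections=(dead,) * 4, stage=stage, polarity=polarity)


def constant_disparity_bank(
    disparity: float = 0.1, n: int = 6, polarity: str = "far"
) -> StimulusBank:
    """Bank whose every trial has the same absolute disparity."""
    signed = disparity if polarity == "far" else -disparity
    scenes = [SceneSpec(target_disparity=signed) for _ in range(n)]
    pairs = [render_stereo(s) for s in scenes]
    return StimulusBank(
        kind=f"absolute_{polarity}",
        seed=0,
        scenes=scenes,
        pairs=pairs,
        labels=np.full(n, signed),
        params={"n": n, "polarity": polarity, "constant": disparity},
    )


@dataclass
class FixtureSet:
    far_bank: StimulusBank
    near_bank: StimulusBank
    relative_bank: StimulusBank
    constant_bank: StimulusBank
    anticorrelated_pair: object
    perfect_responder: Genome
    one_eyed: Genome
    mirror: Genome
    zero_gain: Genome
    expected: dict
    seed: int


def generate_fixtures(seed: int = 0, out_dir=None) -> FixtureSet:
    """Build the deterministic fixture suite (optionally writing it out).

    The relative bank is sized so all three depth-configuration classes
    occur; the "perfect responder" scores zero lifetime error on the
    constant-disparity bank by construction.
    """
    far_bank = make_absolute_bank(12, "far", seed=seed)
    near_bank = make_absolute_bank(12, "near", seed=seed + 1)
    relative_bank = make_relative_bank(48, polarity="rel_far", seed=seed + 2)
    constant = constant_disparity_bank(0.1)
    pair = render_stereo(SceneSpec(target_disparity=0.06))
    fixtures = FixtureSet(
        far_bank=far_bank,
        near_bank=near_bank,
        relative_bank=relative_bank,
        constant_bank=constant,
        anticorrelated_pair=anticorrelate(pair, "contralateral"),
        perfect_responder=constant_genome(0.1),
        one_eyed=one_eyed_genome(),
        mirror=mirror_genome(),
        zero_gain=zero_gain_genome(),
        expected={
            "perfect_responder_lifetime_error": 0.0,
            "one_eyed_odi": 1.0,
            "mirror_odi": 0.0,
            "zero_gain_labels": ["negligible"] * 4,
        },
        seed=seed,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_bank(far_bank, out / "far_bank")
        save_bank(near_bank, out / "near_bank")
        save_bank(relative_bank, out / "relative_bank")
        save_genomes(
            [fixtures.perfect_responder, fixtures.one_eyed, fixtures.mirror, fixtures.zero_gain],
            out / "genomes.json",
            provenance={"seed": seed, "kind": "hand-built fixtures"},
        )
    return fixtures
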