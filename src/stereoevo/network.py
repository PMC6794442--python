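"""Evolvable binocular units and their genomes.

A binocular unit sums four signed-logistic transformations of its four input
lines; every connection's (gain, slope, offset, sign) is evolvable and the
unit's response is read directly as degrees of disparity magnitude.

* Second-order units combine the four monocular activities
  (contra@fixation, ipsi@fixation, contra@target, ipsi@target) and evolve to
  report absolute disparity; far- and near-polarity units evolve separately.
* Third-order units combine the four second-order responses
  (far@target, near@target, far@reference, near@reference) — the reference
  responses come from verbatim clones of the target-position genomes fed by
  the reference monocular pair — and evolve to report relative disparity.

The fixed input-line ordering above is part of the genome contract, so
connectivity classification is unambiguous.  Genomes serialize to JSON.

Populations are carried as float arrays of shape (size, 4, 4) with the last
axis holding (gain, slope, offset, sign); the array and object paths compute
identical responses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .sigmoid import SigmoidParams, logistic

STAGES = ("second_order", "third_order")
POLARITIES = ("far", "near", "rel_far", "rel_near")
N_CONNECTIONS = 4

SECOND_ORDER_INPUTS = ("contra@fixation", "ipsi@fixation", "contra@target", "ipsi@target")
THIRD_ORDER_INPUTS = ("far@target", "near@target", "far@reference", "near@reference")

PARAM_NAMES = ("gain", "slope", "offset", "sign")

# Slope ranges scale with the stage's input scale: monocular activities span
# an order-one range, while second-order responses (the third-order inputs)
# are disparity-coded and an order of magnitude smaller, so third-order
# sigmoids need proportionally steeper slopes to express any nonlinearity
# over their input range.
_SLOPE_HI = {"second_order": 10.0, "third_order": 100.0}


def init_ranges(stage: str) -> dict:
    """Initialisation ranges for "weak but fully connected" genomes."""
    return {
        "gain": (0.0, 0.1),
        "slope": (0.0, _SLOPE_HI[stage]),
        "offset": (-5.0, 5.0),
    }


def param_bounds(stage: str) -> dict:
    """Clipping bounds for mutation; gain may drift above its init range so
    strong connections can emerge."""
    return {
        "gain": (0.0, 1.0),
        "slope": (0.0, _SLOPE_HI[stage]),
        "offset": (-5.0, 5.0),
    }


@dataclass(frozen=True)
class Genome:
    """The evolvable parameters of one binocular unit (four connections)."""

    connections: tuple
    stage: str
    polarity: str

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}")
        if self.polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}")
        if len(self.connections) != N_CONNECTIONS:
            raise ValueError(f"a genome has exactly {N_CONNECTIONS} connections")

    @property
    def input_names(self) -> tuple:
        return SECOND_ORDER_INPUTS if self.stage == "second_order" else THIRD_ORDER_INPUTS

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "polarity": self.polarity,
            "connections": [c.to_dict() for c in self.connections],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Genome":
        return cls(
            connections=tuple(SigmoidParams.from_dict(c) for c in d["connections"]),
            stage=d["stage"],
            polarity=d["polarity"],
        )


def save_genomes(genomes, path, provenance: dict = None) -> None:
    """Write genomes (and optional provenance) to a JSON file."""
    payload = {
        "provenance": provenance or {},
        "genomes": [g.to_dict() for g in genomes],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_genomes(path):
    payload = json.loads(Path(path).read_text())
    return [Genome.from_dict(d) for d in payload["genomes"]]


# ---------------------------------------------------------------------------
# Array codec

def genome_to_array(genome: Genome) -> np.ndarray:
    """(4, 4) array with last axis (gain, slope, offset, sign)."""
    return np.array(
        [[c.gain, c.slope, c.offset, float(c.sign)] for c in genome.connections]
    )


def array_to_genome(row: np.ndarray, stage: str, polarity: str) -> Genome:
    conns = tuple(
        SigmoidParams(gain=float(g), slope=float(b), offset=float(c), sign=int(s))
        for g, b, c, s in np.asarray(row)
    )
    return Genome(connections=conns, stage=stage, polarity=polarity)


def init_population(stage: str, polarity: str, size: int, rng: np.random.Generator) -> np.ndarray:
    """Weak, fully connected random genomes as a (size, 4, 4) array.

    Gains uniform on (0, 0.1), slopes on (0, 10), offsets on (-5, 5), signs
    equiprobable +-1.  Deterministic for a given generator state.
    """
    if stage not in STAGES:
        raise ValueError(f"stage must be one of {STAGES}")
    if polarity not in POLARITIES:
        raise ValueError(f"polarity must be one of {POLARITIES}")
    ranges = init_ranges(stage)
    params = np.empty((size, N_CONNECTIONS, 4))
    for k, name in enumerate(("gain", "slope", "offset")):
        lo, hi = ranges[name]
        params[:, :, k] = rng.uniform(lo, hi, (size, N_CONNECTIONS))
    params[:, :, 3] = rng.choice([-1.0, 1.0], (size, N_CONNECTIONS))
    return params


def init_genome(stage: str, polarity: str, rng: np.random.Generator) -> Genome:
    """One weak, fully connected random genome."""
    return array_to_genome(init_population(stage, polarity, 1, rng)[0], stage, polarity)


# ---------------------------------------------------------------------------
# Forward passes

def _sum_of_sigmoids(inputs, genome: Genome):
    inputs = np.asarray(inputs, dtype=float)
    if inputs.shape[-1] != N_CONNECTIONS:
        raise ValueError(f"expected {N_CONNECTIONS} inputs, got {inputs.shape[-1]}")
    total = np.zeros(inputs.shape[:-1])
    for c, conn in enumerate(genome.connections):
        total = total + logistic(inputs[..., c], conn)
    if total.ndim == 0:
        return float(total)
    return total


def second_order_response(mono_activities, genome: Genome):
    """Second-order (absolute-disparity) response: sum of four sigmoids.

    Input order is fixed as (contra@fixation, ipsi@fixation, contra@target,
    ipsi@target); accepts a length-4 vector or an (n, 4) matrix.
    """
    if genome.stage != "second_order":
        raise ValueError("genome is not a second-order genome")
    return _sum_of_sigmoids(mono_activities, genome)


def third_order_response(second_order_values, genome: Genome):
    """Third-order (relative-disparity) response: sum of four sigmoids.

    Input order is fixed as (far@target, near@target, far@reference,
    near@reference).
    """
    if genome.stage != "third_order":
        raise ValueError("genome is not a third-order genome")
    return _sum_of_sigmoids(second_order_values, genome)


def population_responses(params: np.ndarray, inputs: np.ndarray) -> np.ndarray:
    """Vectorised forward pass for a whole population.

    ``params``: (size, 4, 4) array; ``inputs``: (n, 4) input matrix shared by
    all individuals.  Returns (size, n) responses, bit-equivalent to the
    per-genome path.
    """
    params = np.asarray(params, dtype=float)
    inputs = np.asarray(inputs, dtype=float)
    g = params[:, None, :, 0]
    b = params[:, None, :, 1]
    c = params[:, None, :, 2]
    s = params[:, None, :, 3]
    pre = inputs[None, :, :]
    return np.sum(s * g / (1.0 + np.exp(-b * pre + c)), axis=-1)


def second_order_input_columns(position_index: int) -> list:
    """Activity-matrix columns feeding a second-order unit at a position.

    Position indices follow the assembly order (0 fixation, 1 target,
    2 reference); the unit always also receives the fixation pair.
    """
    if position_index < 1:
        raise ValueError("second-order units sit at the target or reference position")
    return [0, 1, 2 * position_index, 2 * position_index + 1]


def third_order_inputs(
    mono_activities: np.ndarray, far_genome: Genome, near_genome: Genome
) -> np.ndarray:
    """Second-order response matrix feeding the third-order stage.

    ``mono_activities`` is the (n, 6) activity matrix of a relative-stage
    assembly.  The far/near genomes evolved at the target position are
    cloned verbatim at the reference position (only the feeding monocular
    pair differs).  Returns (n, 4) columns in THIRD_ORDER_INPUTS order.
    """
    mono_activities = np.asarray(mono_activities, dtype=float)
    if mono_activities.shape[-1] != 6:
        raise ValueError("relative-stage activities must have six columns")
    at_target = mono_activities[:, second_order_input_columns(1)]
    at_reference = mono_activities[:, second_order_input_columns(2)]
    return np.stack(
        [
            second_order_response(at_target, far_genome),
            second_order_response(at_target, near_genome),
            second_order_response(at_reference, far_genome),
            second_order_response(at_reference, near_genome),
        ],
        axis=-1,
    )
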