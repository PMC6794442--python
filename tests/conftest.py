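"""Shared fixtures.

The desk-scale evolution runs (5 populations x 200 networks x 600
generations) are expensive, so they are session-scoped and shared between
the probe tests and the acceptance suite.  All seeds are fixed constants.
"""

import numpy as np
import pytest

from stereoevo import (
    EvolutionConfig,
    TuningCurve,
    evolve_absolute,
    evolve_relative,
    place_monocular_pairs,
    tuning_curve,
)

FAR_SEED = 101
NEAR_SEED = 102
RELFAR_SEED = 103
RELNEAR_SEED = 104
CONTROL_SEED = 105

PROBE_GRID = np.arange(0.01, 0.18 + 1e-9, 0.01)
SIGNED_GRID = np.arange(-0.18, 0.18 + 1e-9, 0.01)


@pytest.fixture(scope="session")
def absolute_assembly():
    return place_monocular_pairs(stage="absolute")


@pytest.fixture(scope="session")
def relative_assembly():
    return place_monocular_pairs(stage="relative")


@pytest.fixture(scope="session")
def far_run():
    return evolve_absolute(EvolutionConfig.desk(master_seed=FAR_SEED), "far")


@pytest.fixture(scope="session")
def near_run():
    return evolve_absolute(EvolutionConfig.desk(master_seed=NEAR_SEED), "near")


@pytest.fixture(scope="session")
def frozen_pairs(far_run, near_run):
    """Per-population frozen (far, near) second-order genomes."""
    return list(zip(far_run.best_genomes, near_run.best_genomes))


@pytest.fixture(scope="session")
def relfar_run(frozen_pairs):
    return evolve_relative(
        EvolutionConfig.desk(master_seed=RELFAR_SEED), "rel_far", frozen_pairs
    )


@pytest.fixture(scope="session")
def relnear_run(frozen_pairs):
    return evolve_relative(
        EvolutionConfig.desk(master_seed=RELNEAR_SEED), "rel_near", frozen_pairs
    )


@pytest.fixture(scope="session")
def control_run():
    return evolve_absolute(
        EvolutionConfig.desk(master_seed=CONTROL_SEED), "far", randomize_positions=True
    )


@pytest.fixture(scope="session")
def far_curve(far_run, absolute_assembly):
    return tuning_curve(far_run.best_genomes, absolute_assembly, PROBE_GRID)


@pytest.fixture(scope="session")
def near_curve(near_run, absolute_assembly):
    return tuning_curve(near_run.best_genomes, absolute_assembly, -PROBE_GRID)


@pytest.fixture(scope="session")
def pooled_magnitude_curve(far_curve, near_curve):
    """Far and near population curves aligned on disparity magnitude."""
    responses = np.vstack([far_curve.responses, near_curve.responses[:, ::-1]])
    return TuningCurve(PROBE_GRID, responses, "conventional", "second_order", "far")
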