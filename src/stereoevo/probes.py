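"""Physiology-style measurements on evolved binocular units.

All probes are pure functions of genomes + seeds: tuning curves for
conventional and anti-correlated stereograms, response-based ocular
dominance, excitatory/inhibitory/negligible connection classification, the
operational disparity limit, the dominance-vs-depth-tuning correlation, and
the retinotopy-control verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .evolution import RunResult, rebuild_bank, training_targets
from .frontend import MonocularAssembly
from .network import (
    Genome,
    second_order_response,
    third_order_inputs,
    third_order_response,
)
from .sigmoid import logistic
from .stimuli import (
    MAX_DISPARITY,
    SceneSpec,
    StereoPair,
    anticorrelate,
    render_stereo,
)

DEFAULT_ANTICORR_EYE = "contralateral"


# ---------------------------------------------------------------------------
# Shared forward helpers

def _scene_for(disparity: float, stage: str, scene: SceneSpec) -> SceneSpec:
    """Scene probing one disparity.

    Second-order probes vary the target's absolute disparity.  Third-order
    probes realise a relative disparity ``d`` as the symmetric combination
    target = +d/2, reference = -d/2 (one of the many absolute-disparity
    pairs producing the same relative value).
    """
    if stage == "second_order":
        return replace(scene, target_disparity=float(disparity),
                       reference_offset=None, reference_disparity=None)
    return replace(scene, target_disparity=float(disparity) / 2.0,
                   reference_offset=-0.6, reference_disparity=-float(disparity) / 2.0)


def _pair_inputs(
    pair: StereoPair,
    assembly: MonocularAssembly,
    stage: str,
    second_order: Optional[tuple],
) -> np.ndarray:
    acts = assembly.bank_activities([pair])
    if stage == "second_order":
        return acts[:, :4]
    if second_order is None:
        raise ValueError("third-order probes need frozen (far, near) second-order genomes")
    return third_order_inputs(acts, *second_order)


def _respond(inputs: np.ndarray, genome: Genome) -> np.ndarray:
    if genome.stage == "second_order":
        return second_order_response(inputs, genome)
    return third_order_response(inputs, genome)


# ---------------------------------------------------------------------------
# Tuning curves

@dataclass
class TuningCurve:
    """Binocular-unit response versus disparity, aggregated over populations.

    ``responses`` holds one row per probed genome (typically each replicate
    population's best individual); ``mean``/``std`` aggregate across rows.
    """

    disparities: np.ndarray
    responses: np.ndarray
    mode: str
    stage: str
    polarity: str

    def __post_init__(self) -> None:
        self.disparities = np.asarray(self.disparities, dtype=float)
        self.responses = np.atleast_2d(np.asarray(self.responses, dtype=float))
        if self.responses.shape[1] != self.disparities.size:
            raise ValueError("responses and disparities are inconsistent")
        if np.any(np.diff(self.disparities) <= 0):
            raise ValueError("disparities must be strictly increasing")

    @property
    def mean(self) -> np.ndarray:
        return self.responses.mean(axis=0)

    @property
    def std(self) -> np.ndarray:
        return self.responses.std(axis=0)

    @property
    def dynamic_range(self) -> float:
        """Spread of the across-population mean response."""
        return float(self.mean.max() - self.mean.min())


def tuning_curve(
    genomes: Sequence[Genome],
    assembly: MonocularAssembly,
    disparities: Sequence[float],
    mode: str = "conventional",
    second_order: Optional[tuple] = None,
    anticorr_eye: str = DEFAULT_ANTICORR_EYE,
    scene: SceneSpec = SceneSpec(),
) -> TuningCurve:
    """Mean/σ response across genomes as a function of disparity.

    ``mode="anticorrelated"`` contrast-reverses one eye of every probe
    stimulus.  For third-order genomes supply the frozen second-order pair;
    disparities are then relative disparities.
    """
    if mode not in ("conventional", "anticorrelated"):
        raise ValueError("mode must be 'conventional' or 'anticorrelated'")
    genomes = list(genomes)
    stage = genomes[0].stage
    if any(g.stage != stage for g in genomes):
        raise ValueError("all probed genomes must share a stage")
    disparities = np.asarray(sorted(float(d) for d in disparities))
    limit = 2 * MAX_DISPARITY if stage == "third_order" else MAX_DISPARITY
    if np.any(np.abs(disparities) > limit + 1e-12):
        raise ValueError(f"probe disparities exceed the renderable range (+-{limit})")
    rows = np.zeros((len(genomes), disparities.size))
    for j, d in enumerate(disparities):
        pair = render_stereo(_scene_for(d, stage, scene), assembly.geometry)
        if mode == "anticorrelated":
            pair = anticorrelate(pair, anticorr_eye)
        inputs = _pair_inputs(pair, assembly, stage, second_order)
        for i, g in enumerate(genomes):
            rows[i, j] = _respond(inputs, g)[0]
    return TuningCurve(
        disparities=disparities,
        responses=rows,
        mode=mode,
        stage=stage,
        polarity=genomes[0].polarity,
    )


# ---------------------------------------------------------------------------
# Disparity limit

@dataclass(frozen=True)
class DisparityLimit:
    limit: float
    met: bool
    median_errors: np.ndarray = field(default=None, compare=False)


def disparity_limit(curve: TuningCurve, tolerance: float = 0.02) -> DisparityLimit:
    """Operational upper disparity limit of a set of evolved units.

    The largest probed |disparity| at which the median (across populations)
    absolute error between response and disparity magnitude stays within
    ``tolerance`` degrees.  Returns limit 0 with ``met=False`` when no grid
    point qualifies.
    """
    if curve.mode != "conventional":
        raise ValueError("the disparity limit is defined on conventional curves")
    target = np.abs(curve.disparities)
    med = np.median(np.abs(curve.responses - target[None, :]), axis=0)
    ok = med <= tolerance
    if not np.any(ok):
        return DisparityLimit(limit=0.0, met=False, median_errors=med)
    return DisparityLimit(
        limit=float(np.max(target[ok])), met=True, median_errors=med
    )


# ---------------------------------------------------------------------------
# Ocular dominance

@dataclass(frozen=True)
class DominanceRecord:
    """Response-based ocular dominance of one binocular unit.

    ODI = (M_contra - M_ipsi) / (M_contra + M_ipsi) where M is the eye's
    peak-to-trough response modulation under a monocular probe sweep (the
    other eye held at uniform background).  +1 = fully contralateral.
    """

    odi: float
    modulation_contra: float
    modulation_ipsi: float
    degenerate: bool = False
    preferred_disparity: Optional[float] = None


def _monocular_sweep_inputs(
    assembly: MonocularAssembly,
    eye: str,
    sweep: np.ndarray,
    scene: SceneSpec,
) -> np.ndarray:
    """Monocular activity rows for target-edge shifts shown to one eye only."""
    has_ref = assembly.n_pairs == 3
    blank = np.full(assembly.geometry.width_px, scene.background_luminance)
    rows = []
    for s in sweep:
        probe_scene = replace(
            scene,
            target_offset=scene.target_offset + float(s),
            target_disparity=0.0,
            reference_offset=-0.6 if has_ref else None,
            reference_disparity=0.0 if has_ref else None,
        )
        rendered = render_stereo(probe_scene, assembly.geometry)
        kwargs = dict(
            left_profile=blank, right_profile=blank, geometry=assembly.geometry,
            target_disparity=0.0,
            figure_luminance=scene.figure_luminance,
            background_luminance=scene.background_luminance,
        )
        side = StereoPair.eye_labels[eye]
        kwargs[f"{side}_profile"] = rendered.profile(eye)
        rows.append(StereoPair(**kwargs))
    return assembly.bank_activities(rows)


def ocular_dominance_index(
    genome: Genome,
    assembly: MonocularAssembly,
    second_order: Optional[tuple] = None,
    sweep: Optional[np.ndarray] = None,
    scene: SceneSpec = SceneSpec(),
) -> DominanceRecord:
    """Response-based ocular dominance of a second- or third-order unit.

    The target edge is swept monocularly across the unit's field (default
    +-0.09 deg in 25 steps) with the other eye at uniform background; each
    eye's modulation is the peak-to-trough response swing.  A response-based
    index is used because evolved sigmoid nonlinearities make raw gains
    incomparable across connections.
    """
    if sweep is None:
        sweep = np.linspace(-0.09, 0.09, 25)
    modulations = {}
    for eye in ("contralateral", "ipsilateral"):
        mono = _monocular_sweep_inputs(assembly, eye, sweep, scene)
        if genome.stage == "second_order":
            inputs = mono[:, :4]
        else:
            if second_order is None:
                raise ValueError("third-order dominance needs frozen second-order genomes")
            inputs = third_order_inputs(mono, *second_order)
        responses = _respond(inputs, genome)
        modulations[eye] = float(responses.max() - responses.min())
    mc, mi = modulations["contralateral"], modulations["ipsilateral"]
    denom = mc + mi
    if denom <= 1e-12:
        return DominanceRecord(odi=0.0, modulation_contra=mc, modulation_ipsi=mi, degenerate=True)
    return DominanceRecord(odi=(mc - mi) / denom, modulation_contra=mc, modulation_ipsi=mi)


def preferred_disparity(
    genome: Genome,
    assembly: MonocularAssembly,
    disparities: Optional[Sequence[float]] = None,
    second_order: Optional[tuple] = None,
    scene: SceneSpec = SceneSpec(),
) -> float:
    """Disparity of maximal response on the conventional tuning curve."""
    if disparities is None:
        top = 2 * MAX_DISPARITY if genome.stage == "third_order" else MAX_DISPARITY
        disparities = np.arange(-top, top + 1e-9, 0.02)
    curve = tuning_curve([genome], assembly, disparities, "conventional", second_order, scene=scene)
    return float(curve.disparities[int(np.argmax(curve.responses[0]))])


def dominance_records(
    genomes: Sequence[Genome],
    assembly: MonocularAssembly,
    second_order=None,
    scene: SceneSpec = SceneSpec(),
) -> list:
    """ODI + preferred-depth records for a set of genomes.

    ``second_order`` may be a single frozen (far, near) pair or one pair per
    genome.
    """
    genomes = list(genomes)
    if second_order is None or isinstance(second_order[0], Genome):
        pairs = [second_order] * len(genomes)
    else:
        pairs = list(second_order)
    records = []
    for g, so in zip(genomes, pairs):
        rec = ocular_dominance_index(g, assembly, so, scene=scene)
        records.append(
            replace(rec, preferred_disparity=preferred_disparity(g, assembly, second_order=so, scene=scene))
        )
    return records


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int
    degenerate: bool = False


def dominance_tuning_correlation(records: Sequence[DominanceRecord]) -> CorrelationResult:
    """Pearson correlation between depth tuning and ocular dominance.

    Requires >= 3 records with preferred-disparity values; constant inputs
    yield r = 0 with a degenerate flag.
    """
    records = list(records)
    if len(records) < 3:
        raise ValueError("need at least three units")
    odi = np.array([r.odi for r in records])
    depth = np.array([r.preferred_disparity for r in records], dtype=float)
    if np.any(np.isnan(depth)):
        raise ValueError("records lack preferred-disparity values")
    if np.ptp(odi) == 0 or np.ptp(depth) == 0:
        return CorrelationResult(r=0.0, p_value=1.0, n=len(records), degenerate=True)
    r, p = stats.pearsonr(depth, odi)
    return CorrelationResult(r=float(r), p_value=float(p), n=len(records))


# ---------------------------------------------------------------------------
# Connection classification

def classify_connections(
    genome: Genome,
    assembly: MonocularAssembly,
    threshold: float = 0.01,
    second_order: Optional[tuple] = None,
    probe_disparities: Optional[Sequence[float]] = None,
    scene: SceneSpec = SceneSpec(),
) -> list:
    """Label each connection excitatory, inhibitory, or negligible.

    Per-connection contributions are evaluated over a conventional disparity
    sweep; a connection whose output swing is below ``threshold`` times the
    unit's total response range is negligible (little or no effect), and the
    rest are labelled by their sign.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if probe_disparities is None:
        top = 2 * MAX_DISPARITY if genome.stage == "third_order" else MAX_DISPARITY
        probe_disparities = np.arange(-top, top + 1e-9, 0.01)
    inputs = []
    for d in probe_disparities:
        pair = render_stereo(_scene_for(float(d), genome.stage, scene), assembly.geometry)
        inputs.append(_pair_inputs(pair, assembly, genome.stage, second_order)[0])
    inputs = np.asarray(inputs)
    contributions = np.stack(
        [logistic(inputs[:, c], conn) for c, conn in enumerate(genome.connections)],
        axis=1,
    )
    total = contributions.sum(axis=1)
    total_range = float(total.max() - total.min())
    labels = []
    for c, conn in enumerate(genome.connections):
        swing = float(contributions[:, c].max() - contributions[:, c].min())
        if total_range == 0.0 or swing < threshold * total_range:
            labels.append("negligible")
        else:
            labels.append("excitatory" if conn.sign > 0 else "inhibitory")
    return labels


# ---------------------------------------------------------------------------
# Retinotopy control

@dataclass(frozen=True)
class RetinotopyReport:
    """Did depth responses evolve, or did training fail without retinotopy?

    A run counts as evolved only when its final error beats ``factor`` times
    the best-constant-predictor baseline on its own banks.
    """

    control_verdict: str
    retinotopic_verdict: str
    control_population_verdicts: tuple
    retinotopic_population_verdicts: tuple
    control_errors: tuple
    retinotopic_errors: tuple
    baselines: dict


def _run_verdicts(run: RunResult, factor: float):
    mean_errors, baselines, verdicts = [], [], []
    for errors, seed in zip(run.final_errors, run.eval_bank_seeds):
        bank = rebuild_bank(run, seed)
        targets = training_targets(bank)
        baseline = float(np.sum(np.abs(targets - np.median(targets))))
        mean_err = float(np.mean(errors))
        baselines.append(baseline)
        mean_errors.append(mean_err)
        verdicts.append("evolved" if mean_err < factor * baseline else "failed")
    overall = (
        "evolved"
        if np.median(mean_errors) < factor * np.median(baselines)
        else "failed"
    )
    return overall, tuple(verdicts), tuple(mean_errors), baselines


def retinotopy_control_report(
    control_run: RunResult,
    retinotopic_run: RunResult,
    factor: float = 0.8,
) -> RetinotopyReport:
    """Compare position-randomised training against fixed-retinotopy training.

    The constant-predictor baseline is the summed error of the best constant
    response (the median training disparity) on each run's evaluation bank;
    a run whose final median error is not better than ``factor`` times that
    baseline "failed" to evolve.
    """
    for name in ("lifetime_stimuli",):
        if getattr(control_run.config, name) != getattr(retinotopic_run.config, name):
            raise ValueError(f"runs are not comparable: {name} differs")
    if control_run.bank_params["max_disparity"] != retinotopic_run.bank_params["max_disparity"]:
        raise ValueError("runs are not comparable: max_disparity differs")
    c_overall, c_verdicts, c_errors, c_base = _run_verdicts(control_run, factor)
    r_overall, r_verdicts, r_errors, r_base = _run_verdicts(retinotopic_run, factor)
    return RetinotopyReport(
        control_verdict=c_overall,
        retinotopic_verdict=r_overall,
        control_population_verdicts=c_verdicts,
        retinotopic_population_verdicts=r_verdicts,
        control_errors=c_errors,
        retinotopic_errors=r_errors,
        baselines={"control": c_base, "retinotopic": r_base},
    )


# ---------------------------------------------------------------------------
# Plotting

def plot_tuning_curves(curves: Sequence[TuningCurve], path=None, ax=None):
    """Mean +- s.d. tuning curves (error bars = s.d. across populations)."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for curve in curves:
        label = f"{curve.polarity} {curve.mode}"
        color = "0.5" if curve.mode == "conventional" else "k"
        ax.errorbar(curve.disparities, curve.mean, yerr=curve.std, label=label,
                    color=color, marker="o", ms=3, lw=1, capsize=2)
    ax.axhline(0, color="0.8", lw=0.8)
    ax.set_xlabel("disparity (deg)")
    ax.set_ylabel("response (deg-coded)")
    ax.legend(fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
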