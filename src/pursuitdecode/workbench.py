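"""Configuration, HDF5 run container, and the seeded end-to-end runner.

``run_experiment`` executes the full chain for one simulated participant:
stimulus protocol -> synthetic currents/artifacts/sensors -> trial rejection
-> preprocessing -> hierarchical Bayesian inverse -> SLiR decoding ->
generalization matrix -> regional statistics.  Everything is reproducible
from the config and master seed.

``simulate_replicate_task_data`` is the light-weight variant used for
replicate studies: it generates ground-truth reduced currents directly at the
analysis rate and packages them for the decoder, skipping the sensor/inverse
stages (the paper's own decoder consumes the reduced currents).
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field

import h5py
import numpy as np
import pandas as pd
import yaml

from . import evaluate, groupstats, inverse, neurosim, protocol, slir
from .evaluate import TaskData
from .protocol import TASKS

log = logging.getLogger("pursuitdecode")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage

SCHEMA_VERSION = 1
CONTAINER_GROUPS = ("protocol", "truth", "sensors", "inverse", "models", "evaluation", "stats")


@dataclass
class GeneratorConfig:
    n_dipoles: int = 500
    n_sensors: int = 64
    n_trials_per_task: int = 40
    gains: dict = field(default_factory=lambda: dict(neurosim.DEFAULT_GAINS))
    response_lag: float = neurosim.DEFAULT_RESPONSE_LAG
    evoked_amp: float = 40.0
    current_noise_sd: float = 10.0
    sensor_noise_sd: float = 1.0
    heart_rate: float = 1.2
    recordable_range: float | None = None  # None: no rejection applied


@dataclass
class InverseConfig:
    ma_period: int = 9
    target_fs: float = 200.0
    reduction: int = 4
    sigma: float | None = None
    magnification: float = 10.0
    with_extra: bool = True
    max_iter: int = 200
    tol: float = 1e-6


@dataclass
class DecoderConfig:
    tau: int = 6
    dtau: int = 10
    tpred: int = 1
    max_iter: int = 100
    tol: float = 1e-6


@dataclass
class EvaluationConfig:
    folds: int = 10
    n_perm: int = 199
    normalization: str = "by-test"
    alpha: float = 0.05


@dataclass
class RunConfig:
    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    inverse: InverseConfig = field(default_factory=InverseConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        raw = yaml.safe_load(text)
        return cls(
            seed=raw.get("seed", 0),
            generator=GeneratorConfig(**raw.get("generator", {})),
            inverse=InverseConfig(**raw.get("inverse", {})),
            decoder=DecoderConfig(**raw.get("decoder", {})),
            evaluation=EvaluationConfig(**raw.get("evaluation", {})),
        )


@dataclass
class ExperimentResult:
    config: RunConfig
    space: neurosim.SourceSpace
    subpopulations: neurosim.SubpopulationSpec
    forward: neurosim.ForwardModel
    simulated: dict[str, neurosim.SimulatedTask]
    solutions: dict[str, inverse.InverseSolution]
    task_data: dict[str, TaskData]
    matrix: evaluate.GeneralizationMatrix
    normalized: evaluate.NormalizedScores
    region_means: pd.DataFrame  # trial x region x task (long form)
    anova_tables: dict[str, pd.DataFrame]
    sharing: pd.DataFrame
    timings: dict[str, float]


def epoch_targets(task: str, fs: float = 200.0) -> dict[str, np.ndarray]:
    """Target position/velocity on the epoch grid (zero before motion onset)."""
    traj = protocol.task_trajectory(task)
    t = neurosim._epoch_time(fs)
    pos, vel = neurosim._target_on_grid(traj, t)
    return {"position": pos, "velocity": vel}


def run_experiment(config: RunConfig) -> ExperimentResult:
    """Run the full simulated-participant pipeline under one master seed.

    A failure in any stage is re-raised as :class:`StageError` naming the
    stage, so partial runs are diagnosable.
    """
    marker = {"stage": "setup"}
    try:
        return _run_experiment(config, marker)
    except Exception as exc:
        raise StageError(marker["stage"], exc) from exc


def _run_experiment(config: RunConfig, marker: dict) -> ExperimentResult:
    g, timings = config.generator, {}
    t0 = time.perf_counter()

    space = neurosim.make_source_space(g.n_dipoles, seed=config.seed)
    spec = neurosim.make_default_subpopulations(
        space, seed=config.seed + 1, gains=g.gains, response_lag=g.response_lag
    )
    fm = neurosim.make_forward_model(space, g.n_sensors, seed=config.seed + 2)
    timings["setup"] = time.perf_counter() - t0
    log.info("setup: %d dipoles, %d sensors", space.n_dipoles, fm.n_sensors)

    marker["stage"] = "simulate"
    t0 = time.perf_counter()
    simulated = {}
    for k, task in enumerate(TASKS):
        sim = neurosim.simulate_task(
            task, space, spec, fm,
            n_trials=g.n_trials_per_task, seed=config.seed + 100 + k,
            evoked_amp=g.evoked_amp, current_noise_sd=g.current_noise_sd,
            sensor_noise_sd=g.sensor_noise_sd, heart_rate=g.heart_rate,
        )
        if g.recordable_range is not None:
            sim.trials = neurosim.reject_trials(sim.trials, g.recordable_range)
        simulated[task] = sim
    timings["simulate"] = time.perf_counter() - t0

    marker["stage"] = "inverse"
    t0 = time.perf_counter()
    inv_cfg = config.inverse
    smoother, Ghat = inverse.build_smoothing(space, fm.G, sigma=inv_cfg.sigma,
                                             reduction=inv_cfg.reduction)
    prior = inverse.make_region_prior(space, magnification=inv_cfg.magnification)
    vb = inverse.VBSettings(max_iter=inv_cfg.max_iter, tol=inv_cfg.tol)
    solutions = {}
    for task, sim in simulated.items():
        pre = inverse.preprocess(sim.trials, inv_cfg.ma_period, inv_cfg.target_fs)
        solutions[task] = inverse.estimate_currents(
            pre, smoother, Ghat, fm.G_extra, prior, vb, with_extra=inv_cfg.with_extra
        )
    timings["inverse"] = time.perf_counter() - t0
    log.info("inverse: %d reduced dipoles", smoother.n_reduced)

    marker["stage"] = "decode+evaluate"
    t0 = time.perf_counter()
    cfg = slir.SLiRConfig(tau=config.decoder.tau, dtau=config.decoder.dtau,
                          tpred=config.decoder.tpred, fs=inv_cfg.target_fs)
    ard = slir.ARDSettings(max_iter=config.decoder.max_iter, tol=config.decoder.tol)
    task_data = {}
    for task, sol in solutions.items():
        targets = epoch_targets(task, inv_cfg.target_fs)
        n_trials = sol.Z.shape[0]
        task_data[task] = TaskData(
            currents=[sol.Z[i] for i in range(n_trials)],
            targets={r: [targets[r]] * n_trials for r in slir.REGRESSANDS},
        )
    ev = config.evaluation
    matrix = evaluate.build_generalization_matrix(
        task_data, cfg, ard, folds=ev.folds, seed=config.seed + 500, n_perm=ev.n_perm
    )
    normalized = evaluate.normalize_scores([matrix.R2], mode=ev.normalization)
    timings["decode+evaluate"] = time.perf_counter() - t0

    marker["stage"] = "stats"
    t0 = time.perf_counter()
    region_frames = []
    for task, sol in solutions.items():
        df = inverse.regional_mean_per_trial(sol, space)
        df["task"] = task
        df["trial"] = np.arange(len(df))
        region_frames.append(df)
    region_means = pd.concat(region_frames, ignore_index=True)

    anova_tables = {}
    n_blocks = min(
        (region_means["task"] == task).sum() for task in TASKS
    )
    for region in neurosim.TASK_RELEVANT_REGIONS:
        if region not in region_means.columns:
            continue
        mat = np.column_stack(
            [region_means.loc[region_means["task"] == task, region].to_numpy()[:n_blocks]
             for task in TASKS]
        )
        anova_tables[region] = groupstats.rb_anova1(mat)

    selected = {t: matrix.models[t].selected("position") for t in TASKS}
    sharing = evaluate.categorize_shared_dipoles(selected)
    timings["stats"] = time.perf_counter() - t0
    for stage, dt in timings.items():
        log.info("stage %-16s %.2f s", stage, dt)

    return ExperimentResult(
        config=config, space=space, subpopulations=spec, forward=fm,
        simulated=simulated, solutions=solutions, task_data=task_data,
        matrix=matrix, normalized=normalized, region_means=region_means,
        anova_tables=anova_tables, sharing=sharing, timings=timings,
    )


# ---------------------------------------------------------------------------
# replicate-scale data for decoder studies


def simulate_replicate_task_data(
    seed: int,
    n_dipoles: int = 120,
    n_trials: int = 10,
    gains: dict | None = None,
    current_noise_sd: float = 10.0,
    response_lag: float = neurosim.DEFAULT_RESPONSE_LAG,
    fs: float = 200.0,
    evoked_amp: float = 40.0,
) -> tuple[dict[str, TaskData], neurosim.SourceSpace, neurosim.SubpopulationSpec]:
    """Ground-truth decoding data for one replicate (no sensor/inverse stage).

    Currents are simulated directly at the analysis rate on a small source
    space; each task contributes ``n_trials`` trials with the task's target
    series as regressands.
    """
    space = neurosim.make_source_space(n_dipoles, seed=seed)
    spec = neurosim.make_default_subpopulations(space, seed=seed + 1, gains=gains,
                                                response_lag=response_lag)
    rng = np.random.default_rng(seed + 2)
    task_data = {}
    for task in TASKS:
        traj = protocol.task_trajectory(task)
        schedules = protocol.make_trial_schedule(task, n_trials, seed + 3)
        targets = epoch_targets(task, fs)
        currents = []
        for sched in schedules:
            truth = neurosim.simulate_currents(
                space, spec, sched, traj, evoked_amp=evoked_amp,
                noise_sd=current_noise_sd, seed=int(rng.integers(2**31 - 1)), fs=fs,
            )
            currents.append(truth.currents)
        task_data[task] = TaskData(
            currents=currents,
            targets={r: [targets[r]] * n_trials for r in slir.REGRESSANDS},
        )
    return task_data, space, spec


# ---------------------------------------------------------------------------
# HDF5 run container


def write_container(path, result: ExperimentResult) -> None:
    """Serialise the run into an HDF5 container (one group per stage)."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["config"] = result.config.to_yaml()

        gp = f.create_group("protocol")
        for task in TASKS:
            traj = result.simulated[task].trajectory
            tg = gp.create_group(task)
            tg.create_dataset("position", data=traj.position)
            tg.create_dataset("velocity", data=traj.velocity)
            tg.attrs["frequency"] = traj.frequency
            tg.attrs["amplitude"] = traj.amplitude

        gt = f.create_group("truth")
        gs = f.create_group("sensors")
        for task, sim in result.simulated.items():
            gt.create_dataset(f"{task}/currents_trial0", data=sim.truths[0].currents)
            gt.create_dataset(f"{task}/eye_position_trial0", data=sim.truths[0].eye_position)
            gs.create_dataset(f"{task}/data", data=sim.trials.data)
            gs.create_dataset(f"{task}/retained", data=sim.trials.retained)

        gi = f.create_group("inverse")
        for task, sol in result.solutions.items():
            gi.create_dataset(f"{task}/Z", data=sol.Z)
            if sol.extra is not None:
                gi.create_dataset(f"{task}/extra", data=sol.extra)
            gi.create_dataset(f"{task}/alpha", data=sol.alpha)
            gi.create_dataset(f"{task}/objective", data=sol.objective)

        gm = f.create_group("models")
        for task, model in result.matrix.models.items():
            for reg, fit in model.fits.items():
                grp = gm.create_group(f"{task}/{reg}")
                grp.create_dataset("weights", data=fit.weights)
                grp.create_dataset("relevance", data=fit.relevance)
                grp.create_dataset("selected", data=fit.selected)
                grp.attrs["bias"] = fit.bias

        ge = f.create_group("evaluation")
        ge.create_dataset("r", data=result.matrix.r)
        ge.create_dataset("R2", data=result.matrix.R2)
        ge.create_dataset("p_R2", data=result.matrix.p_R2)
        ge.create_dataset("normalized_R2_mean", data=result.normalized.mean)

        gst = f.create_group("stats")
        for region, table in result.anova_tables.items():
            grp = gst.create_group(region)
            grp.create_dataset("F", data=table["F"].to_numpy(float))
            grp.create_dataset("p", data=table["p"].to_numpy(float))
            grp.create_dataset("df", data=table["df"].to_numpy(float))


def read_container(path, require: tuple[str, ...] = CONTAINER_GROUPS) -> dict:
    """Read a run container back into nested dicts of arrays.

    Raises on a schema-version mismatch; missing groups are reported in the
    returned ``missing`` list and flagged via ``complete`` (partial runs are
    readable).
    """
    out: dict = {"groups": {}, "missing": [], "complete": True}
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"container schema version {version} != supported {SCHEMA_VERSION}"
            )
        out["config"] = str(f.attrs.get("config", ""))
        for name in require:
            if name not in f:
                out["missing"].append(name)
                out["complete"] = False
                continue
            out["groups"][name] = _read_group(f[name])
    if out["missing"]:
        log.warning("container %s missing groups: %s", path, out["missing"])
    return out


def _read_group(group) -> dict:
    out = {}
    for key, item in group.items():
        out[key] = _read_group(item) if isinstance(item, h5py.Group) else np.asarray(item)
    out.update({f"@{k}": v for k, v in group.attrs.items()})
    return out
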