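"""Synthetic MEG generator with task-dependent cortical subpopulations.

Ground truth is organised around the task/function hypothesis: a *visual*
subpopulation is driven by the target in every task, an *attention*
subpopulation only during covert and overt pursuit, and an *eye-movement*
(motor) subpopulation only during overt pursuit.  Each active dipole carries a
linear mixture of target position and velocity, led by a fixed response lag
(cortical activity precedes the target).  Extra-brain sources — two eyes and
the heart — generate artifact currents that are projected to the sensors
through their own lead-field columns, so the inverse stage can be tested on
artifact-contaminated data.

Geometry is a desk-scale abstraction: dipoles on a sphere-like shell with
contiguous region patches, sensors on a helmet cap, and a seeded random lead
field with inverse-square distance decay.  It is not a conductor model; it is
deliberately swappable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import protocol
from .protocol import TargetTrajectory, TrialSchedule, task_functions

REGIONS = ("PreCC", "MSFC", "LOTC", "IPC", "Precuneus", "V1V2", "irrelevant")
TASK_RELEVANT_REGIONS = REGIONS[:-1]

DEFAULT_REGION_FRACTIONS = {
    "PreCC": 0.08,
    "MSFC": 0.05,
    "LOTC": 0.10,
    "IPC": 0.10,
    "Precuneus": 0.05,
    "V1V2": 0.12,
    "irrelevant": 0.50,
}

RAW_FS = 1000.0  # Hz
EPOCH_SAMPLES = 4401  # [-0.4, 4.0] s at 1000 Hz
ONSET_INDEX = 400

# amplitude references shared by all tasks so that encodings are linear in the
# physical stimulus: position is expressed in units of the 0.5 Hz amplitude,
# velocity in units of the common 20 deg/s peak.
POS_REF = protocol.PEAK_VELOCITY / (2.0 * np.pi * 0.5)
VEL_REF = protocol.PEAK_VELOCITY

#: default population gains (peak task-locked current, pA*m/mm^2 scale).
#: With the default background noise (sd 10) the visual/attention populations
#: have per-dipole SNR near 1 — single-trial currents are individually weak —
#: while eye-movement-related currents are several times stronger, consistent
#: with the much larger current densities seen under overt pursuit.
DEFAULT_GAINS = {"visual": 10.0, "attention": 8.0, "motor": 30.0}
DEFAULT_RESPONSE_LAG = 0.100  # s; cortical currents lead the target

EYE_POSITIONS = np.array([[-32.0, 90.0, -30.0], [32.0, 90.0, -30.0]])  # mm
HEART_POSITION = np.array([15.0, 0.0, -350.0])  # mm, |offset| per the head model


@dataclass
class SourceSpace:
    """Dipole geometry: positions (mm), unit orientations, region labels."""

    positions: np.ndarray  # (n, 3)
    orientations: np.ndarray  # (n, 3), unit norm
    regions: np.ndarray  # (n,) of str
    seed: int

    @property
    def n_dipoles(self) -> int:
        return self.positions.shape[0]

    def region_indices(self, region: str) -> np.ndarray:
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}")
        return np.flatnonzero(self.regions == region)


@dataclass
class SubpopulationSpec:
    """Functional subpopulations and their task-gated target encodings.

    ``mix`` holds, per population, an (n_members, 2) array of mixing weights
    onto normalised target position and velocity; the encoding is shared
    across tasks, only the gain is gated by the task/function table.
    """

    members: dict[str, np.ndarray]  # population -> dipole indices
    gains: dict[str, dict[str, float]]  # population -> task -> gain
    mix: dict[str, np.ndarray]  # population -> (n_members, 2)
    response_lag: float = DEFAULT_RESPONSE_LAG  # s, >0 = currents lead target

    POP_FUNCTION = {"visual": "visual", "attention": "attention", "motor": "eye_movement"}

    def __post_init__(self) -> None:
        for pop, fn in self.POP_FUNCTION.items():
            for task in protocol.TASKS:
                g = self.gains.get(pop, {}).get(task, 0.0)
                if g != 0.0 and fn not in task_functions(task):
                    raise ValueError(
                        f"population {pop!r} has nonzero gain in task {task!r}, "
                        f"which does not engage {fn!r}"
                    )


@dataclass
class ForwardModel:
    """Lead fields for cortical dipoles and the nine extra-brain columns."""

    G: np.ndarray  # (n_sensors, n_dipoles)
    G_extra: np.ndarray  # (n_sensors, 9): 2 eyes + heart, xyz each
    sensor_positions: np.ndarray  # (n_sensors, 3), mm

    @property
    def n_sensors(self) -> int:
        return self.G.shape[0]


@dataclass
class TrialTruth:
    """Ground-truth currents for a single trial."""

    currents: np.ndarray  # (n_dipoles, n_samples), pA*m/mm^2 scale
    extra: np.ndarray  # (9, n_samples)
    eye_position: np.ndarray  # (n_samples,), deg
    task: str


@dataclass
class TrialSet:
    """Epoched multi-sensor data with task labels and a rejection mask."""

    data: np.ndarray  # (n_trials, n_sensors, n_samples)
    fs: float
    tasks: np.ndarray  # (n_trials,) of str
    epoch_window: tuple[float, float] = protocol.EPOCH_WINDOW
    retained: np.ndarray | None = None  # bool mask; None = all retained

    def __post_init__(self) -> None:
        if self.retained is None:
            self.retained = np.ones(self.data.shape[0], dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def retention_rate(self) -> float:
        return float(np.mean(self.retained))

    def retained_data(self) -> np.ndarray:
        return self.data[self.retained]


def make_source_space(
    n_dipoles: int = 500,
    region_fractions: dict[str, float] | None = None,
    seed: int = 0,
    radius: float = 80.0,
) -> SourceSpace:
    """Place dipoles on a jittered spherical shell with contiguous region patches.

    Regions are grown greedily around seeded anchor directions, so each label
    occupies a spatially contiguous patch whose size matches its fraction.
    """
    if n_dipoles < 50:
        raise ValueError("n_dipoles must be >= 50")
    fractions = dict(DEFAULT_REGION_FRACTIONS if region_fractions is None else region_fractions)
    missing = set(fractions) - set(REGIONS)
    if missing:
        raise ValueError(f"unknown regions in fractions: {sorted(missing)}")
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"region fractions must sum to 1 (got {total})")

    rng = np.random.default_rng(seed)
    directions = rng.normal(size=(n_dipoles, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    radii = radius * (1.0 + 0.05 * rng.standard_normal(n_dipoles))
    positions = directions * radii[:, None]
    orientations = rng.normal(size=(n_dipoles, 3))
    orientations /= np.linalg.norm(orientations, axis=1, keepdims=True)

    # largest-remainder apportioning of dipole counts to regions
    order = [r for r in REGIONS if fractions.get(r, 0.0) > 0]
    raw = np.array([fractions[r] * n_dipoles for r in order])
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts))[: n_dipoles - counts.sum()]:
        counts[i] += 1

    regions = np.empty(n_dipoles, dtype=object)
    unassigned = np.ones(n_dipoles, dtype=bool)
    anchors = rng.normal(size=(len(order), 3))
    anchors /= np.linalg.norm(anchors, axis=1, keepdims=True)
    for region, count, anchor in zip(order, counts, anchors):
        idx = np.flatnonzero(unassigned)
        d = np.linalg.norm(positions[idx] - radius * anchor, axis=1)
        take = idx[np.argsort(d)[:count]]
        regions[take] = region
        unassigned[take] = False
    regions = regions.astype(str)
    return SourceSpace(positions=positions, orientations=orientations, regions=regions, seed=seed)


def make_forward_model(
    space: SourceSpace,
    n_sensors: int = 64,
    eye_positions: np.ndarray | None = None,
    heart_position: np.ndarray | None = None,
    seed: int = 0,
    helmet_radius: float = 110.0,
) -> ForwardModel:
    """Seeded random lead field with inverse-square distance decay.

    Each sensor gets a fixed random pickup direction; the coupling of dipole
    ``k`` to sensor ``s`` is the projection of the dipole orientation onto
    that direction (plus a small seeded perturbation for full rank), divided
    by the squared source-sensor distance.  The same construction yields the
    nine extra-brain columns (two eyes + heart, three orthogonal directions
    each).
    """
    if n_sensors < 10:
        raise ValueError("n_sensors must be >= 10 for a meaningful inverse")
    eye_positions = EYE_POSITIONS if eye_positions is None else np.asarray(eye_positions, float)
    heart_position = HEART_POSITION if heart_position is None else np.asarray(heart_position, float)

    rng = np.random.default_rng(seed)
    # helmet cap: deterministic Fibonacci lattice over the upper shell
    i = np.arange(n_sensors)
    z = 0.15 + 0.85 * (i + 0.5) / n_sensors
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(1.0 - z**2)
    sensors = helmet_radius * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])

    pickup = rng.normal(size=(n_sensors, 3))
    pickup /= np.linalg.norm(pickup, axis=1, keepdims=True)

    def lead_columns(pos: np.ndarray, ori: np.ndarray) -> np.ndarray:
        # pos: (m, 3); ori: (m, 3) -> (n_sensors, m)
        diff = sensors[:, None, :] - pos[None, :, :]
        d2 = np.sum(diff**2, axis=2)  # mm^2
        coupling = pickup @ ori.T + 0.2 * rng.standard_normal((n_sensors, pos.shape[0]))
        return coupling * (100.0**2 / d2)

    G = lead_columns(space.positions, space.orientations)
    extra_pos = np.vstack([eye_positions, heart_position[None, :]])
    eye = np.repeat(extra_pos, 3, axis=0)  # (9, 3)
    dirs = np.tile(np.eye(3), (3, 1))  # xyz per source
    G_extra = lead_columns(eye, dirs)
    return ForwardModel(G=G, G_extra=G_extra, sensor_positions=sensors)


def make_default_subpopulations(
    space: SourceSpace,
    seed: int = 0,
    gains: dict[str, float] | None = None,
    response_lag: float = DEFAULT_RESPONSE_LAG,
    member_fraction: float = 0.6,
) -> SubpopulationSpec:
    """Assign functional subpopulations to the task-relevant regions.

    Visual members are drawn from V1/V2 and LOTC, attention members from the
    parieto-frontal attention regions (IPC, Precuneus, MSFC, LOTC), and motor
    (eye-movement) members from the precentral cortex.  ``member_fraction`` of
    each candidate pool is recruited.
    """
    g = dict(DEFAULT_GAINS if gains is None else gains)
    rng = np.random.default_rng(seed)
    pools = {
        "visual": np.concatenate([space.region_indices("V1V2"), space.region_indices("LOTC")]),
        "attention": np.concatenate(
            [space.region_indices(r) for r in ("IPC", "Precuneus", "MSFC", "LOTC")]
        ),
        "motor": space.region_indices("PreCC"),
    }
    members, mix = {}, {}
    for pop, pool in pools.items():
        k = max(1, int(round(member_fraction * pool.size)))
        members[pop] = np.sort(rng.choice(pool, size=k, replace=False))
        # unit-norm random (position, velocity) mixing weights per member
        m = rng.standard_normal((k, 2))
        mix[pop] = m / np.linalg.norm(m, axis=1, keepdims=True)
    task_gains = {
        "visual": {t: g["visual"] for t in protocol.TASKS},
        "attention": {
            t: (g["attention"] if "attention" in task_functions(t) else 0.0)
            for t in protocol.TASKS
        },
        "motor": {
            t: (g["motor"] if "eye_movement" in task_functions(t) else 0.0)
            for t in protocol.TASKS
        },
    }
    return SubpopulationSpec(members=members, gains=task_gains, mix=mix, response_lag=response_lag)


def _epoch_time(fs: float = RAW_FS) -> np.ndarray:
    n = int(round((protocol.EPOCH_WINDOW[1] - protocol.EPOCH_WINDOW[0]) * fs)) + 1
    return protocol.EPOCH_WINDOW[0] + np.arange(n) / fs


def _target_on_grid(trajectory: TargetTrajectory, t: np.ndarray, shift: float = 0.0):
    """Analytic position/velocity at times ``t + shift``; zero outside motion."""
    ts = t + shift
    omega = 2.0 * np.pi * trajectory.frequency
    on = (ts >= 0) & (ts <= protocol.MOTION_DURATION)
    pos = np.where(on, trajectory.amplitude * np.sin(omega * ts), 0.0)
    vel = np.where(on, trajectory.peak_velocity * np.cos(omega * ts), 0.0)
    return pos, vel


def simulate_currents(
    space: SourceSpace,
    spec: SubpopulationSpec,
    schedule: TrialSchedule,
    trajectory: TargetTrajectory,
    evoked_amp: float = 40.0,
    noise_sd: float = 10.0,
    seed: int = 0,
    fs: float = RAW_FS,
) -> TrialTruth:
    """Ground-truth cortical currents for one trial.

    Active populations carry ``gain(task) * (a_i * pos + b_i * vel)`` evaluated
    ``response_lag`` seconds ahead of the target (cortex leads), the visual
    population additionally carries an evoked transient ~0.1 s after motion
    onset, and every dipole receives white background noise.
    """
    t = _epoch_time(fs)
    epoch_len = protocol.EPOCH_WINDOW[1] - protocol.EPOCH_WINDOW[0]
    if abs(spec.response_lag) >= epoch_len:
        raise ValueError("response lag exceeds the epoch bounds")
    for pop, idx in spec.members.items():
        if idx.size and (idx.min() < 0 or idx.max() >= space.n_dipoles):
            raise ValueError(f"population {pop!r} indexes outside the source space")

    rng = np.random.default_rng(seed)
    J = noise_sd * rng.standard_normal((space.n_dipoles, t.size)) if noise_sd > 0 else np.zeros(
        (space.n_dipoles, t.size)
    )

    pos, vel = _target_on_grid(trajectory, t, shift=spec.response_lag)
    pos_n, vel_n = pos / POS_REF, vel / VEL_REF
    task = schedule.task
    for pop, idx in spec.members.items():
        gain = spec.gains[pop].get(task, 0.0)
        if gain == 0.0 or idx.size == 0:
            continue
        a, b = spec.mix[pop][:, 0], spec.mix[pop][:, 1]
        J[idx] += gain * (np.outer(a, pos_n) + np.outer(b, vel_n))

    if evoked_amp != 0.0:
        bump = np.exp(-0.5 * ((t - 0.1) / 0.03) ** 2)
        vis = spec.members["visual"]
        if vis.size:
            polarity = np.sign(spec.mix["visual"][:, 0] + 1e-12)
            J[vis] += evoked_amp * np.outer(polarity, bump)

    return TrialTruth(currents=J, extra=np.zeros((9, t.size)), eye_position=np.zeros(t.size), task=task)


def simulate_artifacts(
    schedule: TrialSchedule,
    trajectory: TargetTrajectory,
    task: str,
    heart_rate: float = 1.2,
    blink_rate: float = 0.15,
    seed: int = 0,
    fs: float = RAW_FS,
    eye_gain: float = 400.0,
    heart_amp: float = 2.0e4,
    pursuit_delay: float = 0.08,
    fixation_jitter_sd: float = 0.15,
) -> tuple[np.ndarray, np.ndarray]:
    """Extra-brain source currents (9 x samples) and the eye-position trace.

    Overt tasks: horizontal eye-dipole currents track the target (with a small
    oculomotor delay and tracking noise).  Covert/control: low-pass fixation
    jitter plus occasional blink transients on the vertical components.  A
    smooth cardiac pulse train at ``heart_rate`` loads the heart dipoles in
    every task.
    """
    if not 0.5 < heart_rate < 3.0:
        raise ValueError("heart_rate must lie in (0.5, 3) Hz")
    rng = np.random.default_rng(seed)
    t = _epoch_time(fs)
    n = t.size

    # slow fixation jitter: heavily smoothed white noise, bounded ~0.5 deg
    jitter = rng.standard_normal(n)
    kernel = np.exp(-0.5 * ((np.arange(-300, 301)) / 100.0) ** 2)
    kernel /= kernel.sum()
    jitter = np.convolve(jitter, kernel, mode="same")
    jitter *= fixation_jitter_sd / max(jitter.std(), 1e-12)

    if task.startswith("overt"):
        pos, _ = _target_on_grid(trajectory, t, shift=-pursuit_delay)
        eye = pos + 0.3 * jitter
    else:
        eye = jitter

    extra = np.zeros((9, n))
    # horizontal (x) components of both eye dipoles follow eye position
    extra[0] = eye_gain * eye
    extra[3] = eye_gain * eye * 0.95  # slight left/right asymmetry
    # vertical components: blink transients (all tasks can blink)
    n_blinks = rng.poisson(blink_rate * (t[-1] - t[0]))
    for _ in range(n_blinks):
        t0 = rng.uniform(t[0] + 0.2, t[-1] - 0.2)
        bump = np.exp(-0.5 * ((t - t0) / 0.06) ** 2)
        extra[2] += 3.0 * eye_gain * bump
        extra[5] += 3.0 * eye_gain * bump
    # cardiac pulse train: von-Mises-shaped so the fundamental dominates
    phase0 = rng.uniform(0, 2 * np.pi)
    pulse = np.exp(3.0 * (np.cos(2 * np.pi * heart_rate * t + phase0) - 1.0))
    pulse -= pulse.mean()
    extra[6] = heart_amp * pulse
    extra[7] = 0.6 * heart_amp * pulse
    extra[8] = 0.3 * heart_amp * pulse
    return extra, eye


def synthesize_sensors(
    fm: ForwardModel,
    truth: TrialTruth,
    sensor_noise_sd: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Project cortical + extra-brain currents to sensors and add white noise."""
    if fm.G.shape[1] != truth.currents.shape[0]:
        raise ValueError("forward model / current dimensions disagree")
    if truth.extra.shape[0] != fm.G_extra.shape[1]:
        raise ValueError("extra-current dimensions disagree")
    B = fm.G @ truth.currents + fm.G_extra @ truth.extra
    if sensor_noise_sd > 0:
        rng = np.random.default_rng(seed)
        B = B + sensor_noise_sd * rng.standard_normal(B.shape)
    return B


def reject_trials(
    trials: TrialSet,
    recordable_range: float,
    threshold_fraction: float = 0.95,
) -> TrialSet:
    """Mark trials whose signal exceeds ``threshold_fraction`` of the recordable range.

    A trial is rejected when any sample on any channel exceeds the threshold;
    retained trials keep their original ordering.
    """
    if recordable_range <= 0:
        raise ValueError("recordable_range must be positive")
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must lie in (0, 1]")
    limit = threshold_fraction * recordable_range
    peak = np.max(np.abs(trials.data), axis=(1, 2))
    return replace(trials, retained=peak <= limit)


@dataclass
class SimulatedTask:
    """All trials of one task: sensor set, per-trial ground truth, trajectory."""

    trials: TrialSet
    truths: list[TrialTruth]
    trajectory: TargetTrajectory
    task: str


def simulate_task(
    task: str,
    space: SourceSpace,
    spec: SubpopulationSpec,
    fm: ForwardModel,
    n_trials: int = 40,
    seed: int = 0,
    evoked_amp: float = 40.0,
    current_noise_sd: float = 10.0,
    sensor_noise_sd: float = 1.0,
    heart_rate: float = 1.2,
) -> SimulatedTask:
    """Simulate one task block end to end (schedules, currents, artifacts, sensors)."""
    schedules = protocol.make_trial_schedule(task, n_trials, seed)
    trajectory = protocol.task_trajectory(task)
    rng = np.random.default_rng(seed + 1)
    truths, data = [], []
    for sched in schedules:
        s1, s2, s3 = rng.integers(0, 2**31 - 1, size=3)
        truth = simulate_currents(
            space, spec, sched, trajectory, evoked_amp=evoked_amp,
            noise_sd=current_noise_sd, seed=int(s1),
        )
        extra, eye = simulate_artifacts(sched, trajectory, task, heart_rate=heart_rate, seed=int(s2))
        truth.extra, truth.eye_position = extra, eye
        data.append(synthesize_sensors(fm, truth, sensor_noise_sd, seed=int(s3)))
        truths.append(truth)
    trials = TrialSet(data=np.stack(data), fs=RAW_FS, tasks=np.array([task] * n_trials))
    return SimulatedTask(trials=trials, truths=truths, trajectory=trajectory, task=task)
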