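"""Pursuit-target stimulus and trial scheduling.

Five task conditions are modelled: a control condition (fixate, ignore the
moving target), covert pursuit at 0.5 and 0.8 Hz (track the target with
attention while fixating) and overt pursuit at 0.5 and 0.8 Hz (smooth-pursuit
eye movements).  The target moves sinusoidally in the horizontal plane with a
fixed peak velocity, so the amplitude is determined by the frequency:
``amplitude = peak_velocity / (2 pi f)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TASKS = ("control", "covert_0.5", "covert_0.8", "overt_0.5", "overt_0.8")

#: Which neural functions each task engages.  The generative hypothesis is
#: that control requires visual processing only, covert pursuit adds
#: attentional tracking, and overt pursuit additionally recruits eye-movement
#: control.
TASK_FUNCTIONS = {
    "control": frozenset({"visual"}),
    "covert_0.5": frozenset({"visual", "attention"}),
    "covert_0.8": frozenset({"visual", "attention"}),
    "overt_0.5": frozenset({"visual", "attention", "eye_movement"}),
    "overt_0.8": frozenset({"visual", "attention", "eye_movement"}),
}

#: Target-motion frequency per task (Hz).  The control task shows the same
#: 0.5 Hz motion as covert/overt 0.5 Hz; only the instruction differs.
TASK_FREQUENCY = {
    "control": 0.5,
    "covert_0.5": 0.5,
    "covert_0.8": 0.8,
    "overt_0.5": 0.5,
    "overt_0.8": 0.8,
}

PEAK_VELOCITY = 20.0  # deg/s, shared by all tasks
MOTION_DURATION = 4.0  # s
EPOCH_WINDOW = (-0.4, 4.0)  # s relative to motion onset
FIXATION_DURATION = 2.0  # s
PRE_MOTION_MEAN = 2.0  # s, jittered uniformly +/- jitter
PRE_MOTION_JITTER = 0.5  # s


@dataclass(frozen=True)
class TargetTrajectory:
    """Sinusoidal target kinematics on a regular time grid.

    ``position(t) = A sin(2 pi f t)`` for ``t >= 0`` and zero before motion
    onset; velocity is the analytic derivative.  ``A = peak_velocity / (2 pi f)``.
    """

    time: np.ndarray  # s, relative to motion onset
    position: np.ndarray  # deg of visual angle
    velocity: np.ndarray  # deg/s
    frequency: float  # Hz
    peak_velocity: float  # deg/s
    amplitude: float  # deg
    fs: float  # Hz

    def __post_init__(self) -> None:
        for name in ("time", "position", "velocity"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))


@dataclass(frozen=True)
class TrialSchedule:
    """Timing of a single trial: fixation, jittered pre-motion hold, motion."""

    task: str
    trial: int
    fixation_duration: float = FIXATION_DURATION
    pre_motion_duration: float = PRE_MOTION_MEAN
    motion_duration: float = MOTION_DURATION
    epoch_window: tuple[float, float] = field(default=EPOCH_WINDOW)


def make_target_trajectory(
    frequency: float,
    peak_velocity: float = PEAK_VELOCITY,
    duration: float = MOTION_DURATION,
    fs: float = 200.0,
    *,
    pre_onset: float = 0.0,
    phase: float = 0.0,
) -> TargetTrajectory:
    """Build the sinusoidal target trajectory.

    Parameters
    ----------
    frequency
        Oscillation frequency in Hz (0.5 or 0.8 in the experiment).
    peak_velocity
        Peak target speed in deg/s; fixes the amplitude at
        ``peak_velocity / (2 pi frequency)``.
    duration
        Motion duration in seconds.
    fs
        Sampling rate of the returned grid, Hz.
    pre_onset
        Length of stationary pre-motion baseline to prepend, seconds.
        Position and velocity are zero there (target at screen centre).
    phase
        Phase offset in radians at motion onset; 0 starts at the centre
        moving at peak velocity.
    """
    if frequency <= 0 or peak_velocity <= 0 or duration <= 0 or fs <= 0:
        raise ValueError("frequency, peak_velocity, duration and fs must be positive")
    if fs < 2 * frequency:
        raise ValueError(f"fs={fs} violates the Nyquist bound for frequency={frequency}")
    if pre_onset < 0:
        raise ValueError("pre_onset must be non-negative")

    amplitude = peak_velocity / (2.0 * np.pi * frequency)
    n_pre = int(round(pre_onset * fs))
    n_motion = int(round(duration * fs))
    time = (np.arange(n_pre + n_motion) - n_pre) / fs
    omega = 2.0 * np.pi * frequency
    moving = time >= 0
    position = np.where(moving, amplitude * np.sin(omega * time + phase), 0.0)
    velocity = np.where(moving, peak_velocity * np.cos(omega * time + phase), 0.0)
    return TargetTrajectory(
        time=time,
        position=position,
        velocity=velocity,
        frequency=frequency,
        peak_velocity=peak_velocity,
        amplitude=amplitude,
        fs=fs,
    )


def task_trajectory(task: str, fs: float = 200.0, *, pre_onset: float = 0.0) -> TargetTrajectory:
    """Trajectory for a named task (frequency looked up, 20 deg/s peak)."""
    _check_task(task)
    return make_target_trajectory(TASK_FREQUENCY[task], PEAK_VELOCITY, MOTION_DURATION, fs, pre_onset=pre_onset)


def make_trial_schedule(
    task: str,
    n_trials: int,
    seed: int,
    *,
    jitter: float = PRE_MOTION_JITTER,
) -> list[TrialSchedule]:
    """Generate ``n_trials`` trial schedules with jittered pre-motion holds.

    The pre-motion hold is drawn uniformly from ``2.0 +/- jitter`` seconds,
    deterministically for a fixed seed.
    """
    _check_task(task)
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if jitter < 0:
        raise ValueError("jitter must be non-negative")
    rng = np.random.default_rng(seed)
    holds = PRE_MOTION_MEAN + rng.uniform(-jitter, jitter, size=n_trials)
    return [
        TrialSchedule(task=task, trial=i, pre_motion_duration=float(h))
        for i, h in enumerate(holds)
    ]


def task_functions(task: str) -> frozenset[str]:
    """Neural functions engaged by a task (visual / attention / eye_movement)."""
    _check_task(task)
    return TASK_FUNCTIONS[task]


def schedules_to_frame(schedules: list[TrialSchedule]) -> pd.DataFrame:
    """Tabulate schedules as (task, trial, pre_motion_s) for CSV export."""
    return pd.DataFrame(
        {
            "task": [s.task for s in schedules],
            "trial": [s.trial for s in schedules],
            "pre_motion_s": [s.pre_motion_duration for s in schedules],
        }
    )


def _check_task(task: str) -> None:
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
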