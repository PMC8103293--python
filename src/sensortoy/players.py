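"""Synthetic cohort generator: virtual children playing the cube games.

The study population this emulates is elementary-school children (6-9 y)
whose fine motor skill is summarised by an age-normed percentile; children
at or below the 16th percentile are flagged as likely to have fine motor
development problems (label 1).  Since no raw data are deposited, this
module provides the data-generating process for the whole pipeline: a
latent skill in [0, 1] drives (a) a percentile and hence the label, and
(b) a control model governing how well the virtual child handles the cube,
so that label-bearing structure exists in both the inertial and the game
channel.

The motion model is kinematic.  The child tries to bring a target direction
(the dot's cell for roadrunner; a tilt pulse toward the intended next cell
for the maze) to the top of the cube.  The world-up direction expressed in
the body frame, ``u(t)``, relaxes toward the target with a critically
damped second-order lag (rate = ``gain``) after a reaction ``latency``,
plus band-limited orientation wobble.  Gyroscope output is the angular velocity consistent
with ``u``'s motion (plus spin about the vertical and measurement noise);
the accelerometer reports the gravity vector in the body frame
(``-9.81 * u``) plus translational jitter.  Tracking bandwidth stays below
~1 Hz by construction, well under the 4 Hz analysis filter, so skill is
observable in the filtered features.

Lower skill means lower gain, longer latency, more wobble and jitter, and a
higher probability of wrong maze steps — every mapping monotone, documented
in :func:`control_model`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.signal import lfilter

from .cube import CubeTopology, build_topology
from .games import (
    MAZE,
    MAZE_STEP_S,
    ROADRUNNER,
    LevelSchedule,
    MazeLayout,
    SessionLog,
    run_maze,
    run_roadrunner,
)

SAMPLE_RATE_HZ = 110.0
GRAVITY = 9.81
ACC_LIMIT = 8.0 * GRAVITY               # +/- 8 G sensitivity
GYRO_LIMIT = np.deg2rad(2000.0)         # 2000 dps sensitivity
PERCENTILE_CUTOFF = 16                  # <= 16 -> label 1
WOBBLE_CORNER_HZ = 2.0                  # part of the wobble survives the 4 Hz filter


@dataclass(frozen=True)
class ChildProfile:
    """One virtual child.

    ``skill`` is the latent fine-motor ability that sets the percentile and
    hence the label.  ``control_skill`` is the same ability as expressed in
    cube handling — the games and the pegboard-style test measure related
    but not identical constructs, so the two differ by a per-child offset.
    ``activity`` is a skill-independent movement-intensity trait (how
    vigorously the child swings the cube when steering deliberately).
    """

    id: str
    age: float                 # years
    gender: str                # "girl" | "boy"
    skill: float               # latent, in [0, 1]
    percentile: int
    label: int
    control_skill: Optional[float] = None   # defaults to skill
    activity: float = 1.0                   # dimensionless, ~U(0.5, 1.5)

    def __post_init__(self) -> None:
        if not 0.0 <= self.skill <= 1.0:
            raise ValueError("skill must lie in [0, 1]")
        if self.control_skill is not None and not 0.0 <= self.control_skill <= 1.0:
            raise ValueError("control_skill must lie in [0, 1]")

    @property
    def handling_skill(self) -> float:
        return self.skill if self.control_skill is None else self.control_skill


@dataclass(frozen=True)
class SensorStream:
    """One session's inertial record on the uniform 110 Hz grid.

    ``up_truth`` is the simulator's internally known world-up direction in
    the body frame (unit rows); it never leaves the package in serialized
    form and exists so tests can compare recovered quantities against
    ground truth.
    """

    t: np.ndarray          # seconds from session start
    acc: np.ndarray        # (n, 3) m/s^2, gravity included
    gyro: np.ndarray       # (n, 3) rad/s
    rate: float = SAMPLE_RATE_HZ
    up_truth: Optional[np.ndarray] = None


@dataclass(frozen=True)
class ControlModel:
    """Skill-dependent handling parameters of a virtual child."""

    gain: float              # 1/s, orientation-error feedback strength
    latency: float           # s, reaction delay
    wobble_sd: float         # rad/s, low-frequency angular noise
    jitter_sd: float         # m/s^2, translational noise
    maze_error_rate: float   # probability per step of a wrong move
    gyro_noise_sd: float = 0.02   # rad/s, white measurement noise
    spin_sd: float = 0.05         # rad/s, incidental spin about the up axis

    def __post_init__(self) -> None:
        for name in ("gain", "latency", "wobble_sd", "jitter_sd", "maze_error_rate",
                     "gyro_noise_sd", "spin_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def control_model(skill: float) -> ControlModel:
    """Map latent skill to handling parameters (each monotone in 1 - skill)."""
    w = 1.0 - skill
    return ControlModel(
        gain=1.5 + 4.5 * skill,
        latency=0.08 + 0.35 * w,
        wobble_sd=0.05 + 0.9 * w,
        jitter_sd=0.3 + 1.7 * w,
        maze_error_rate=0.04 + 0.16 * w,
    )


def skill_to_percentile(skill: float) -> int:
    """Monotone latent-skill -> percentile map (documented convention)."""
    return int(np.clip(np.round(100.0 * float(skill) ** 1.5), 0, 100))


@dataclass(frozen=True)
class CohortConfig:
    """Two-component skill mixture: a low-skill and a typical-skill group.

    The low component sits almost entirely below the percentile-16 boundary
    (skill ~ 0.30) and the typical component almost entirely above it, so
    the label-1 fraction tracks the mixture weight (the prevalence).
    """

    low_mean: float = 0.18
    low_sd: float = 0.05
    typical_mean: float = 0.62
    typical_sd: float = 0.12
    age_low: float = 6.5
    age_high: float = 9.0
    #: SD of the per-child gap between tested skill and cube-handling skill
    control_skill_sd: float = 0.12
    activity_low: float = 0.5
    activity_high: float = 1.5


def sample_cohort(
    n: int,
    prevalence: float,
    seed: int,
    *,
    config: CohortConfig = CohortConfig(),
) -> list[ChildProfile]:
    """Draw ``n`` virtual children; expected label-1 fraction = prevalence."""
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie strictly between 0 and 1")
    if n < 0:
        raise ValueError("n must be nonnegative")
    rng = np.random.default_rng(seed)
    children: list[ChildProfile] = []
    for i in range(n):
        low = rng.random() < prevalence
        mean, sd = (config.low_mean, config.low_sd) if low else (config.typical_mean, config.typical_sd)
        skill = float(np.clip(rng.normal(mean, sd), 0.0, 1.0))
        percentile = skill_to_percentile(skill)
        children.append(
            ChildProfile(
                id=f"c{i:04d}",
                age=float(rng.uniform(config.age_low, config.age_high)),
                gender="girl" if rng.random() < 0.5 else "boy",
                skill=skill,
                percentile=percentile,
                label=int(percentile <= PERCENTILE_CUTOFF),
                control_skill=float(np.clip(rng.normal(skill, config.control_skill_sd), 0.0, 1.0)),
                activity=float(rng.uniform(config.activity_low, config.activity_high)),
            )
        )
    return children


# ---------------------------------------------------------------------------
# sensor synthesis
# ---------------------------------------------------------------------------

def _lowpassed_noise(rng: np.random.Generator, n: int, cols: int, sd: float,
                     corner_hz: float, fs: float) -> np.ndarray:
    """First-order low-passed Gaussian noise with stationary per-axis std ``sd``."""
    if sd == 0.0:
        return np.zeros((n, cols))
    a = 1.0 - np.exp(-2.0 * np.pi * corner_hz / fs)
    white = rng.standard_normal((n, cols))
    y = lfilter([a], [1.0, -(1.0 - a)], white, axis=0)
    return y * (sd * np.sqrt((2.0 - a) / a))


def _track_up(
    d: np.ndarray,
    fs: float,
    model: ControlModel,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Lagged tracking of target directions; returns (u, omega_true).

    ``u`` is the unit world-up-in-body trajectory, ``omega_true`` the body
    angular velocity consistent with it (d u/dt = -omega x u) plus spin
    about u, before measurement noise.  The lag is a critically damped
    second-order response (two cascaded poles at ``gain``): arm movements
    are C1-smooth, so commanded angular velocity is continuous and the
    motion's spectral content stays well below the analysis filter band.
    """
    n = d.shape[0]
    dt = 1.0 / fs
    lag = int(round(model.latency * fs))
    if lag > 0:
        d = np.vstack([np.repeat(d[:1], lag, axis=0), d[:-lag]])
    beta = 1.0 - np.exp(-model.gain * dt)
    u = d
    for _ in range(2):
        zi = (1.0 - beta) * u[:1]  # steady start at the first target
        u, _ = lfilter([beta], [1.0, -(1.0 - beta)], u, axis=0, zi=zi)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    # orientation wobble: band-limited angular noise, amplitude = rate / corner pulsation
    angle_sd = model.wobble_sd / (2.0 * np.pi * WOBBLE_CORNER_HZ)
    wob = _lowpassed_noise(rng, n, 3, angle_sd, WOBBLE_CORNER_HZ, fs)
    u = u + wob
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.gradient(u, dt, axis=0)
    omega = np.cross(v, u)
    spin = _lowpassed_noise(rng, n, 1, model.spin_sd, WOBBLE_CORNER_HZ, fs)
    omega = omega + spin * u
    return u, omega


def _maze_targets(
    log: SessionLog,
    times: np.ndarray,
    topo: CubeTopology,
    tilt_amp: float,
    fs: float,
) -> np.ndarray:
    """Target direction: current cell centre plus tilt pulses toward each step.

    Moving the dot requires tipping the cube toward the next cell; the pulse
    spans the 0.25 s before each executed step.  This task-driven motion is
    common to all children (its amplitude is a skill-independent per-child
    trait), which keeps the maze's inertial channel only weakly informative
    about skill — the precision game stresses planning, not smoothness.
    """
    cells = log.cell_at_times(times)
    d = topo.centers[cells].copy()
    moves = log.dot_moves()
    for prev, move in zip(moves, moves[1:]):
        if move.t <= 0:
            continue
        lead = topo.centers[move.cell] - topo.centers[prev.cell]
        i0 = max(0, int(np.ceil((move.t - 0.25) * fs)))
        i1 = min(len(times), int(np.ceil(move.t * fs)))
        d[i0:i1] += tilt_amp * lead
    return d / np.linalg.norm(d, axis=1, keepdims=True)


def _maze_controller(model: ControlModel, topo: CubeTopology):
    """Plan the next track cell; err to a random neighbour with the model's rate.

    After a wrong step the child walks back to the cell it left before
    resuming the track, which makes time-off-path roughly proportional to
    the error rate.
    """
    state = {"last_good": None, "idx": None}

    def ctrl(t: float, cell: int, layout: MazeLayout, rng: np.random.Generator) -> Optional[int]:
        if layout.on_path(cell):
            i = layout.path_cells.index(cell)
            state["last_good"] = cell
            intended = layout.path_cells[(i + 1) % len(layout.path_cells)]
        else:
            intended = state["last_good"] if state["last_good"] is not None else layout.path_cells[0]
            if not topo.are_adjacent(cell, intended):
                # drifted further off: step toward any neighbour nearer the track
                intended = topo.neighbors(cell)[0]
        if rng.random() < model.maze_error_rate:
            nbs = topo.neighbors(cell)
            return nbs[rng.integers(len(nbs))]
        return intended

    return ctrl


def simulate_session(
    child: ChildProfile,
    game: str,
    schedule: LevelSchedule,
    seed: int,
    *,
    topology: Optional[CubeTopology] = None,
    model: Optional[ControlModel] = None,
    permutation_id: Optional[int] = None,
) -> tuple[SensorStream, SessionLog]:
    """Simulate one child playing one game; returns the paired IMU stream and log.

    ``model`` overrides the skill-derived control model (tests use this to
    switch off noise terms).  Determinism: identical arguments give
    identical outputs; the engine and the sensor noise use independent
    streams spawned from ``seed``.
    """
    topo = topology or build_topology()
    mdl = model if model is not None else control_model(child.handling_skill)
    ss = np.random.SeedSequence(seed)
    engine_seed, sensor_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    fs = SAMPLE_RATE_HZ
    n = int(round(schedule.total_duration * fs))
    times = np.arange(n) / fs
    rng = np.random.default_rng(sensor_seed)

    if game == ROADRUNNER:
        log = run_roadrunner(schedule, engine_seed, topology=topo,
                             child_id=child.id, permutation_id=permutation_id)
        d = topo.centers[log.cell_at_times(times)]
    elif game == MAZE:
        ctrl = _maze_controller(mdl, topo)
        log = run_maze(schedule, ctrl, engine_seed, topology=topo, child_id=child.id)
        if model is None:
            # Steering the dot takes big deliberate swings whose vigour is a
            # personal style, not a skill: in the maze the inertial channel
            # is dominated by that style, with only a residue of the motor
            # noise that dominates the (nearly stationary) roadrunner grip.
            mdl = replace(
                mdl,
                wobble_sd=0.3 * mdl.wobble_sd + 0.4 * child.activity,
                jitter_sd=0.3 * mdl.jitter_sd + 1.5 * child.activity,
            )
        tilt_amp = 0.3 + 0.5 * (child.activity - 0.5)
        d = _maze_targets(log, times, topo, tilt_amp, fs)
    else:
        raise ValueError(f"unknown game: {game}")

    u, omega = _track_up(d, fs, mdl, rng)
    gyro = omega
    if mdl.gyro_noise_sd > 0:
        gyro = gyro + rng.normal(0.0, mdl.gyro_noise_sd, size=omega.shape)
    acc = -GRAVITY * u
    if mdl.jitter_sd > 0:
        acc = acc + rng.normal(0.0, mdl.jitter_sd, size=u.shape)
    stream = SensorStream(
        t=times,
        acc=np.clip(acc, -ACC_LIMIT, ACC_LIMIT),
        gyro=np.clip(gyro, -GYRO_LIMIT, GYRO_LIMIT),
        rate=fs,
        up_truth=u,
    )
    return stream, log


def true_alignment(stream: SensorStream, log: SessionLog,
                   topology: Optional[CubeTopology] = None) -> np.ndarray:
    """Ground-truth dot/up cosine from the simulator's internal state."""
    if stream.up_truth is None:
        raise ValueError("stream carries no ground-truth orientation")
    topo = topology or build_topology()
    cells = log.cell_at_times(stream.t)
    return np.einsum("ij,ij->i", topo.centers[cells], stream.up_truth)


def noise_free(model: ControlModel) -> ControlModel:
    """The same child with every stochastic term switched off."""
    return replace(model, wobble_sd=0.0, jitter_sd=0.0, maze_error_rate=0.0,
                   gyro_noise_sd=0.0, spin_sd=0.0)
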