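"""Closed-loop corridor behavior: simulation and behavioral metrics.

A head-fixed mouse runs on a ball in a tactile virtual reality corridor.
The lateral position of two motorized walls is coupled to locomotion: if
the animal runs at speed ``v`` (cm/s) with run angle ``phi`` (deg) through
a corridor bending at ``psi`` (deg), the snout-to-wall distance ``u`` (mm)
updates by

    du = gamma * v * sin(eps) * dt,   eps = phi - psi

so running toward a wall brings it closer. This module simulates that loop
(with a synthetic tracking policy standing in for the animal), open-loop
trials in which a wall follows a fixed motion schedule regardless of
locomotion, and the behavioral metrics used to quantify tracking: angle
error, wall-distance bias under stimulation, the running mask, and the
closed-loop "illusory corridor" photostimulus power law.

Conventions: the *right* wall is taken as contralateral to the recorded
hemisphere. Lateral offset ``x`` (mm) is positive toward the right wall,
so ``u_right = halfwidth - x`` and ``u_left = halfwidth + x``; corridor
width is conserved by construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: mm of wall motion per cm of locomotion-scale displacement
MM_PER_CM = 10.0

BEHAVIOR_COLUMNS = ["t", "v", "phi", "u_left", "u_right", "trial_id", "wall_velocity"]


@dataclass(frozen=True)
class CouplingParams:
    """Parameters of the wall-coupling update and corridor geometry.

    Parameters
    ----------
    gain
        Dimensionless coupling gain ``gamma``.
    dt
        Update interval in seconds. The default (2 ms) matches the spike
        binning used downstream so behavior and ephys share one clock.
    corridor_halfwidth
        Snout-to-wall distance (mm) when the animal is centered.
    min_wall_distance
        Closest approach of a wall to the face (mm); walls are clamped here.
    trial_length
        Length of one corridor trial, in cm of distance run.
    """

    gain: float = 1.0
    dt: float = 0.002
    corridor_halfwidth: float = 19.0
    min_wall_distance: float = 4.0
    trial_length: float = 200.0

    def __post_init__(self) -> None:
        if not (self.dt > 0):
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not (self.corridor_halfwidth > self.min_wall_distance >= 0):
            raise ValueError(
                "need corridor_halfwidth > min_wall_distance >= 0, got "
                f"{self.corridor_halfwidth}, {self.min_wall_distance}"
            )
        if not (self.trial_length > 0):
            raise ValueError("trial_length must be positive")

    @property
    def max_wall_distance(self) -> float:
        """Farthest wall distance (mm) consistent with width conservation."""
        return 2.0 * self.corridor_halfwidth - self.min_wall_distance

    @property
    def max_offset(self) -> float:
        """Largest |lateral offset| (mm) before a wall clamps."""
        return self.corridor_halfwidth - self.min_wall_distance


@dataclass(frozen=True)
class OpenLoopSchedule:
    """Wall motion schedule for an open-loop trial.

    The contralateral wall ramps from its start position to the hold
    distance over ``move_in_s``, holds for ``hold_s``, and ramps back over
    ``move_out_s``. Defaults follow the 4-s extracellular-recording trial
    structure (1 s in, 2 s hold, 1 s out); use :func:`imaging_schedule`
    for the 8-s imaging structure (2/4/2 s).
    """

    move_in_s: float = 1.0
    hold_s: float = 2.0
    move_out_s: float = 1.0
    start_distance: float | None = None  # default: corridor_halfwidth

    @property
    def duration(self) -> float:
        return self.move_in_s + self.hold_s + self.move_out_s


def imaging_schedule() -> OpenLoopSchedule:
    """The 8-s open-loop schedule used during imaging (2 s in, 4 s hold, 2 s out)."""
    return OpenLoopSchedule(move_in_s=2.0, hold_s=4.0, move_out_s=2.0)


@dataclass(frozen=True)
class CorridorTrial:
    """One trial of the winding corridor.

    ``turn_angle`` is the bend angle psi in degrees (e.g. +/-5.7, +/-11.3,
    16.7, 0). ``mode`` is ``closed_loop``, ``open_loop`` or ``illusory``
    (illusory trials run the same closed loop but with the photostimulus
    substituting for walls). ``open_loop_distance`` (mm) must be given
    iff mode is ``open_loop``.
    """

    turn_angle: float = 0.0
    mode: str = "closed_loop"
    open_loop_distance: float | None = None
    stim_condition: str = "none"
    schedule: OpenLoopSchedule | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("closed_loop", "open_loop", "illusory"):
            raise ValueError(f"unknown trial mode {self.mode!r}")
        if (self.mode == "open_loop") != (self.open_loop_distance is not None):
            raise ValueError("open_loop_distance must be present iff mode='open_loop'")


@dataclass(frozen=True)
class TrackingPolicy:
    """Synthetic controller standing in for the animal.

    ``ideal`` sets the run angle equal to the bend angle at all times (a
    perfect tracker). ``proportional`` steers against the wall-distance
    asymmetry it senses: ``phi = steering_gain * (u_right - u_left)``
    (deg per mm). ``noisy`` adds an angular random walk with increment SD
    ``noise_sd * sqrt(dt)`` (deg per sqrt-second) on top of the
    proportional term. Run speed is constant at ``speed`` cm/s, or drawn
    once per trial from N(speed, speed_sd) truncated at 0.5 cm/s.
    """

    kind: str = "ideal"
    steering_gain: float = 0.0
    noise_sd: float = 0.0
    speed: float = 20.0
    speed_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("ideal", "proportional", "noisy"):
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if self.kind == "noisy" and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def update_wall_position(
    v: float, phi: float, psi: float, params: CouplingParams
) -> float:
    """Single coupling update du = gamma * v * sin(phi - psi) * dt, in mm.

    ``v`` is run speed in cm/s; angles are in degrees. The return value is
    the wall displacement in mm for one ``dt`` step (positive toward the
    right wall under this module's sign convention). The caller is
    responsible for clamping the resulting distances to
    ``[min_wall_distance, max_wall_distance]``.
    """
    v, phi, psi = float(v), float(phi), float(psi)
    if not (np.isfinite(v) and np.isfinite(phi) and np.isfinite(psi)):
        raise ValueError("non-finite input to update_wall_position")
    eps = np.deg2rad(phi - psi)
    return params.gain * v * np.sin(eps) * params.dt * MM_PER_CM


def _trial_speed(policy: TrackingPolicy, rng: np.random.Generator) -> float:
    if policy.speed_sd > 0:
        return float(max(0.5, rng.normal(policy.speed, policy.speed_sd)))
    return float(policy.speed)


def simulate_trial(
    trial: CorridorTrial,
    policy: TrackingPolicy,
    params: CouplingParams,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate one trial; returns a BehaviorTimeSeries DataFrame.

    Closed-loop (and illusory) trials integrate the coupling equation with
    the policy's run angle until the distance run reaches
    ``params.trial_length``; wall distances are clamped to
    ``[min_wall_distance, max_wall_distance]`` so corridor width is
    conserved. Open-loop trials move the contralateral (right) wall along
    the trial's :class:`OpenLoopSchedule` regardless of locomotion, with
    the ipsilateral wall held out of reach.

    Columns: ``t, v, phi, u_left, u_right, trial_id, wall_velocity`` with
    ``wall_velocity`` the discrete time derivative of ``u_right`` (mm/s).
    Deterministic given the seed.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if trial.mode == "open_loop":
        df = _simulate_open_loop(trial, policy, params, rng)
    else:
        df = _simulate_closed_loop(trial, policy, params, rng)
    df["trial_id"] = 0
    df["wall_velocity"] = np.gradient(df["u_right"].to_numpy(), params.dt)
    return df[BEHAVIOR_COLUMNS]


def _simulate_closed_loop(
    trial: CorridorTrial,
    policy: TrackingPolicy,
    params: CouplingParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    psi = trial.turn_angle
    v = _trial_speed(policy, rng)
    n_steps = int(np.ceil(params.trial_length / (v * params.dt)))
    t = np.arange(n_steps) * params.dt
    x = 0.0  # lateral offset, mm (positive toward right wall)
    noise = 0.0
    xs = np.empty(n_steps)
    phis = np.empty(n_steps)
    n_clamped = 0
    for i in range(n_steps):
        if policy.kind == "ideal":
            phi = psi
        else:
            phi = policy.steering_gain * (-2.0 * x)
            if policy.kind == "noisy":
                noise += rng.normal(0.0, policy.noise_sd * np.sqrt(params.dt))
                phi += noise
        xs[i] = x
        phis[i] = phi
        x += update_wall_position(v, phi, psi, params)
        if abs(x) > params.max_offset:
            x = float(np.clip(x, -params.max_offset, params.max_offset))
            n_clamped += 1
    if n_clamped:
        logger.info("clamped wall position on %d of %d steps", n_clamped, n_steps)
    return pd.DataFrame(
        {
            "t": t,
            "v": v,
            "phi": phis,
            "u_left": params.corridor_halfwidth + xs,
            "u_right": params.corridor_halfwidth - xs,
        }
    )


def _simulate_open_loop(
    trial: CorridorTrial,
    policy: TrackingPolicy,
    params: CouplingParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    sched = trial.schedule or OpenLoopSchedule()
    start = sched.start_distance
    if start is None:
        start = params.corridor_halfwidth
    hold = float(trial.open_loop_distance)
    if not (params.min_wall_distance <= hold <= params.max_wall_distance):
        raise ValueError(
            f"open_loop_distance {hold} outside "
            f"[{params.min_wall_distance}, {params.max_wall_distance}]"
        )
    dt = params.dt
    n_in = int(round(sched.move_in_s / dt))
    n_hold = int(round(sched.hold_s / dt))
    n_out = int(round(sched.move_out_s / dt))
    u_right = np.concatenate(
        [
            np.linspace(start, hold, n_in, endpoint=False),
            np.full(n_hold, hold),
            np.linspace(hold, start, n_out, endpoint=False),
        ]
    )
    n = u_right.size
    t = np.arange(n) * dt
    v = _trial_speed(policy, rng)
    return pd.DataFrame(
        {
            "t": t,
            "v": v,
            "phi": trial.turn_angle,
            "u_left": params.max_wall_distance,
            "u_right": u_right,
        }
    )


def simulate_session(
    trials: list[CorridorTrial],
    policy: TrackingPolicy,
    params: CouplingParams,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a sequence of trials on one continuous session clock.

    Trials are concatenated back to back; ``trial_id`` indexes into
    ``trials`` and ``t`` is continuous across the session.
    ``wall_velocity`` is computed within trial boundaries only.
    """
    if not trials:
        raise ValueError("no trials to simulate")
    rng = np.random.default_rng(seed)
    parts = []
    t_offset = 0.0
    for i, trial in enumerate(trials):
        df = simulate_trial(trial, policy, params, rng)
        df["t"] = df["t"] + t_offset
        df["trial_id"] = i
        t_offset = df["t"].iloc[-1] + params.dt
        parts.append(df)
    return pd.concat(parts, ignore_index=True)


def angle_error(traj: pd.DataFrame, trial: CorridorTrial) -> float:
    """Absolute difference |phi - psi| (deg) at the end of the turn.

    Evaluated at the final sample of the trajectory.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    return float(abs(traj["phi"].iloc[-1] - trial.turn_angle))


def wall_distance_bias(
    stim_trials: list[pd.DataFrame],
    unstim_trials: list[pd.DataFrame],
    wall: str = "u_right",
) -> float:
    """Wall-distance bias (mm) of stimulated relative to unstimulated trials.

    Mean over stimulated trials of the end-of-trial wall distance, minus
    the mean wall distance across all unstimulated-trial samples. Signed:
    positive means stimulation pushed the animal away from that wall.
    """
    if not stim_trials or not unstim_trials:
        raise ValueError("need at least one trial in each group")
    end_distances = [float(tr[wall].iloc[-1]) for tr in stim_trials]
    unstim_mean = float(np.mean(np.concatenate([tr[wall].to_numpy() for tr in unstim_trials])))
    return float(np.mean(end_distances) - unstim_mean)


def illusory_power(
    lateral_offset: float, params: CouplingParams, max_power: float = 4.5
) -> tuple[float, float]:
    """Closed-loop photostimulus power (mW) for the illusory corridor.

    Power scales linearly from 0 at the corridor center to ``max_power``
    at the edge. The hemisphere *opposite* the offset side is stimulated:
    a positive (rightward) offset drives the left hemisphere. Returns
    ``(left_mW, right_mW)``. Offsets beyond the edge are clamped with a
    warning.
    """
    offset = float(lateral_offset)
    if abs(offset) > params.corridor_halfwidth:
        warnings.warn(
            f"lateral offset {offset} mm beyond corridor edge; clamping",
            stacklevel=2,
        )
        offset = float(np.clip(offset, -params.corridor_halfwidth, params.corridor_halfwidth))
    power = max_power * abs(offset) / params.corridor_halfwidth
    if offset > 0:
        return (power, 0.0)
    if offset < 0:
        return (0.0, power)
    return (0.0, 0.0)


def running_mask(v: np.ndarray, threshold: float = 3.0) -> np.ndarray:
    """Boolean mask of running epochs: speed strictly greater than threshold (cm/s)."""
    return np.asarray(v) > threshold


# ---------------------------------------------------------------------------
# I/O


def save_behavior(df: pd.DataFrame, path) -> None:
    """Write a behavior time series to CSV or an HDF5 file (by extension)."""
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "w") as f:
            g = f.create_group("behavior")
            for col in BEHAVIOR_COLUMNS:
                g.create_dataset(col, data=df[col].to_numpy())
    else:
        df.to_csv(path, index=False)


def load_behavior(path) -> pd.DataFrame:
    """Read a behavior time series written by :func:`save_behavior`."""
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "r") as f:
            g = f["behavior"]
            return pd.DataFrame({col: g[col][()] for col in BEHAVIOR_COLUMNS})
    return pd.read_csv(path)
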