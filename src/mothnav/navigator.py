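"""Memoryless cast-and-surge navigation agent.

The agent mimics a male moth tracking a pheromone plume: a single sensor
gives a binary above/below-threshold odour reading and a (noisy) local wind
vector, and the only internal state is a countdown timer.  Each detection
puts the agent into SURGE (upwind flight) and resets the timer to
``surge_duration``; when the timer runs out without a fresh detection the
agent falls back to CAST, sweeping crosswind with a sign flip every half
casting period while drifting slightly upwind.  Commanded velocities pass
through an acceleration limiter so manoeuvres are no longer instantaneous,
and all sensor inputs carry Gaussian noise whose standard deviation is a
fixed fraction (default 2%) of the running-average input signal.

Repeated detections extend surging without storing any history, which is how
"exploitation proportional to the acquired signal" coexists with a memoryless
controller: the proportionality knob is ``surge_duration``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .plume import PlumeConfig, PuffPlume, WindState, step_wind
from .segmentation import Trajectory

__all__ = [
    "Mode",
    "SensorConfig",
    "AgentConfig",
    "AgentState",
    "FlightRecord",
    "add_sensor_noise",
    "sense",
    "decide",
    "clamp_acceleration",
    "simulate_flight",
    "mean_path",
]


class Mode(Enum):
    SURGE = "o"  # exploitation: upwind toward the source
    CAST = "s"  # exploration: crosswind sweeps


@dataclass
class SensorConfig:
    """Binary odour sensor + wind sensor with multiplicative-scale noise."""

    detection_threshold: float = 2.0  # concentration units, strict >
    noise_mu: float = 0.0
    noise_sigma_fraction: float = 0.02  # sigma = fraction * running mean signal
    running_mean_tau: float = 1.0  # s, EWMA time constant for the signal mean

    def __post_init__(self) -> None:
        if self.detection_threshold <= 0:
            raise ValueError("detection_threshold must be > 0")
        if self.noise_sigma_fraction < 0:
            raise ValueError("noise_sigma_fraction must be >= 0")


@dataclass
class AgentConfig:
    """Flight-controller parameters (speeds m/s, durations s)."""

    max_speed: float = 1.2
    max_acceleration: float = 12.0  # m/s^2
    surge_speed: float = 0.8
    cast_speed: float = 0.7
    surge_duration: float = 0.5
    cast_period: float = 1.0  # full left-right cycle; sign flips each half
    cast_upwind_drift: float = 0.08  # m/s of upwind creep while casting
    heading_tau: float = 0.4  # s, EWMA smoothing of the sensed upwind direction
    vertical_gain: float = 2.0  # 1/s proportional centring toward z = 0
    vertical_max_speed: float = 0.2
    success_radius: float = 0.1  # m
    max_flight_time: float = 25.0  # s

    def __post_init__(self) -> None:
        for name in ("max_speed", "max_acceleration", "surge_speed", "cast_speed",
                     "surge_duration", "cast_period", "success_radius",
                     "max_flight_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if max(self.surge_speed, self.cast_speed) > self.max_speed:
            raise ValueError("surge/cast speed must not exceed max_speed")


@dataclass
class AgentState:
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(3))
    mode: Mode = Mode.CAST
    timer: float = 0.0
    cast_sign: float = 1.0
    cast_clock: float = 0.0  # time since last cast sign flip
    last_detection_time: float | None = None
    upwind_direction: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))


@dataclass
class FlightRecord:
    """One simulated flight plus its ground-truth behavioural labels."""

    trajectory: Trajectory
    true_modes: np.ndarray  # (n,) of 's' / 'o'
    switch_indices: np.ndarray  # strictly increasing indices where mode changed
    success: bool
    seed: int

    def __post_init__(self) -> None:
        if self.true_modes.shape[0] != self.trajectory.n:
            raise ValueError("one mode label per sample required")


class _RunningMean:
    """Exponentially weighted mean of |signal|, the '2% of average input' base."""

    def __init__(self, tau: float, dt: float):
        self.alpha = min(1.0, dt / tau)
        self.value: np.ndarray | float | None = None

    def update(self, x):
        ax = np.abs(x)
        self.value = ax if self.value is None else self.value + self.alpha * (ax - self.value)
        return self.value


def add_sensor_noise(signal, cfg: SensorConfig, running_mean, rng) -> np.ndarray | float:
    """Add Gaussian noise N(mu, (fraction * running_mean)^2) to a signal.

    Works elementwise for vector signals (each component uses its own
    running-mean scale).  With fraction 0 and mu 0 the signal is returned
    unchanged.
    """
    sig = np.asarray(signal, dtype=float)
    rm = np.asarray(running_mean, dtype=float)
    if np.any(rm < 0):
        raise ValueError("running_mean must be >= 0")
    sd = cfg.noise_sigma_fraction * rm
    noisy = sig + cfg.noise_mu
    if np.any(sd > 0):
        noisy = noisy + sd * rng.standard_normal(sig.shape if sig.shape else None)
    return noisy if sig.shape else float(noisy)


def sense(plume: PuffPlume, wind: WindState, state: AgentState, cfg: SensorConfig,
          conc_mean: _RunningMean, wind_mean: _RunningMean,
          rng: np.random.Generator) -> tuple[bool, np.ndarray]:
    """Local, noisy sensing: binary odour detection + wind vector.

    Only the concentration and wind *at the agent's position* are read
    (strict locality); detection uses a strict > threshold comparison.
    """
    conc = plume.concentration_at(state.position)
    u = wind.instantaneous
    cm = conc_mean.update(conc)
    wm = wind_mean.update(u)
    noisy_conc = add_sensor_noise(conc, cfg, cm, rng)
    noisy_wind = add_sensor_noise(u, cfg, wm, rng)
    return bool(noisy_conc > cfg.detection_threshold), np.asarray(noisy_wind)


def decide(state: AgentState, detected: bool, sensed_wind: np.ndarray,
           cfg: AgentConfig, dt: float) -> np.ndarray:
    """Cast/surge state machine; returns the commanded velocity.

    Detection -> SURGE upwind with the timer reset; timer expiry -> CAST
    crosswind with the cast sign flipping every half ``cast_period``.  The
    upwind direction comes from the sensed wind (horizontal projection); if
    the sensed wind is degenerate the last known direction is reused.
    Mutates ``state`` (mode, timer, cast bookkeeping) in place.
    """
    w = np.asarray(sensed_wind, dtype=float)
    horiz = np.array([w[0], w[1], 0.0])
    norm = np.linalg.norm(horiz)
    if norm > 1e-9:
        # low-pass the heading: a moth holds its course against gusts
        beta = min(1.0, dt / cfg.heading_tau) if cfg.heading_tau > 0 else 1.0
        mixed = (1.0 - beta) * state.upwind_direction + beta * (-horiz / norm)
        mnorm = np.linalg.norm(mixed)
        if mnorm > 1e-9:
            state.upwind_direction = mixed / mnorm
    up = state.upwind_direction
    cross = np.array([-up[1], up[0], 0.0])  # horizontal, perpendicular to upwind

    if detected:
        state.mode = Mode.SURGE
        state.timer = cfg.surge_duration
    elif state.mode is Mode.SURGE:
        state.timer -= dt
        if state.timer <= 0.0:
            state.mode = Mode.CAST
            state.timer = 0.0
            state.cast_clock = 0.0
            state.cast_sign = -state.cast_sign  # start each cast the other way

    vz = float(np.clip(-cfg.vertical_gain * state.position[2],
                       -cfg.vertical_max_speed, cfg.vertical_max_speed))
    if state.mode is Mode.SURGE:
        cmd = cfg.surge_speed * up
    else:
        # harmonic crosswind sweep: lateral speed cs*sin(2*pi*t/cp), so the
        # sweep direction reverses once per cast_period and the turn is smooth
        state.cast_clock += dt
        sweep = np.sin(2.0 * np.pi * state.cast_clock / cfg.cast_period)
        cmd = (cfg.cast_speed * state.cast_sign * sweep * cross
               + cfg.cast_upwind_drift * up)
    cmd = cmd + np.array([0.0, 0.0, vz])
    return cmd


def clamp_acceleration(current_velocity: np.ndarray, commanded_velocity: np.ndarray,
                       max_acceleration: float, dt: float,
                       max_speed: float = np.inf) -> np.ndarray:
    """Truncate the commanded velocity change to |dv|/dt <= max_acceleration,
    then cap the speed at ``max_speed``.  max_acceleration = inf recovers the
    original instant-manoeuvring behaviour."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    cur = np.asarray(current_velocity, dtype=float)
    dv = np.asarray(commanded_velocity, dtype=float) - cur
    dv_max = max_acceleration * dt
    norm = np.linalg.norm(dv)
    if norm > dv_max:
        dv = dv * (dv_max / norm)
    new = cur + dv
    speed = np.linalg.norm(new)
    if speed > max_speed:
        new = new * (max_speed / speed)
    return new


def simulate_flight(plume_cfg: PlumeConfig, wind: WindState, agent_cfg: AgentConfig,
                    sensor_cfg: SensorConfig, seed: int,
                    start_position=(0.0, 0.0, 0.0),
                    spin_up_time: float = 12.0) -> FlightRecord:
    """Run one full flight and record the ground-truth behavioural labels.

    The plume is pre-integrated for ``spin_up_time`` before the agent is
    released (a moth takes off into an established plume, triggered by the
    pheromone it has already received).  The flight ends on success (within
    ``success_radius`` of the source), on leaving the domain, or at
    ``max_flight_time``.  Fully reproducible from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    wind_rng, plume_rng, sensor_rng = (np.random.default_rng(s) for s in ss.spawn(3))
    wind = WindState(mean_velocity=wind.mean_velocity.copy(),
                     turbulence_intensity=wind.turbulence_intensity,
                     correlation_time=wind.correlation_time,
                     rng=wind_rng)
    plume = PuffPlume(plume_cfg, rng=plume_rng)
    dt = plume_cfg.dt

    t = -spin_up_time
    while t < 0.0:
        wind = step_wind(wind, dt)
        plume.release(t, dt)
        plume.advect_and_grow(wind, dt)
        t += dt

    state = AgentState(position=np.asarray(start_position, dtype=float).copy())
    conc_mean = _RunningMean(sensor_cfg.running_mean_tau, dt)
    wind_mean = _RunningMean(sensor_cfg.running_mean_tau, dt)
    lo, hi = plume_cfg.domain_bounds[:, 0], plume_cfg.domain_bounds[:, 1]
    source = plume_cfg.source_position

    times, positions, modes = [], [], []
    success = False
    t = 0.0
    n_steps = int(round(agent_cfg.max_flight_time / dt))
    for _ in range(n_steps):
        detected, sensed_wind = sense(plume, wind, state, sensor_cfg,
                                      conc_mean, wind_mean, sensor_rng)
        cmd = decide(state, detected, sensed_wind, agent_cfg, dt)
        state.velocity = clamp_acceleration(state.velocity, cmd,
                                            agent_cfg.max_acceleration, dt,
                                            agent_cfg.max_speed)
        if detected:
            state.last_detection_time = t

        times.append(t)
        positions.append(state.position.copy())
        modes.append(state.mode.value)

        state.position = state.position + state.velocity * dt
        wind = step_wind(wind, dt)
        plume.release(t, dt)
        plume.advect_and_grow(wind, dt)
        t += dt

        if np.linalg.norm(state.position - source) <= agent_cfg.success_radius:
            success = True
            times.append(t)
            positions.append(state.position.copy())
            modes.append(state.mode.value)
            break
        if np.any(state.position < lo) or np.any(state.position > hi):
            break

    traj = Trajectory(times=np.array(times), positions=np.array(positions),
                      sample_rate=1.0 / dt)
    mode_arr = np.array(modes)
    switches = np.nonzero(mode_arr[1:] != mode_arr[:-1])[0] + 1
    return FlightRecord(trajectory=traj, true_modes=mode_arr,
                        switch_indices=switches, success=success, seed=seed)


def mean_path(flights: list[FlightRecord] | list[Trajectory]) -> Trajectory:
    """Average route over a batch of flights (the 'principal behaviour').

    Flights of different lengths are resampled to the longest flight's
    length by linear interpolation over normalised time, then averaged
    pointwise.  All flights must share the sampling rate.
    """
    if len(flights) == 0:
        raise ValueError("need at least one flight")
    trajs = [f.trajectory if isinstance(f, FlightRecord) else f for f in flights]
    rates = {round(tr.sample_rate, 9) for tr in trajs}
    if len(rates) > 1:
        raise ValueError("all flights must share the sampling rate")
    n_max = max(tr.n for tr in trajs)
    grid = np.linspace(0.0, 1.0, n_max)
    acc = np.zeros((n_max, 3))
    for tr in trajs:
        s = np.linspace(0.0, 1.0, tr.n)
        for c in range(3):
            acc[:, c] += np.interp(grid, s, tr.positions[:, c])
    acc /= len(trajs)
    dt = 1.0 / trajs[0].sample_rate
    return Trajectory(times=np.arange(n_max) * dt, positions=acc,
                      sample_rate=trajs[0].sample_rate)
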