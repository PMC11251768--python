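"""Puff-based pheromone plume in a fluctuating wind.

The plume is a collection of Gaussian puffs ("odour pockets") released from a
point source at a fixed frequency and advected downwind.  Each puff carries a
fixed odour mass Q; as it grows by turbulent diffusion its peak concentration
dilutes.  The wind is a mean vector plus a per-component Ornstein-Uhlenbeck
fluctuation whose stationary r.m.s. equals ``turbulence_intensity`` times the
mean speed.  On top of the shared fluctuation each puff receives independent
random-walk jitter (also scaled by the intensity) so that nearby puffs
decorrelate into distinct pockets rather than a coherent filament.

Coordinate convention: right-handed, metres, origin at the agent release
point; the source sits 2 m upwind at (+2, 0, 0) and the mean wind blows
along -x (from the source toward the release point).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "WindState",
    "Puff",
    "PlumeConfig",
    "PuffPlume",
    "step_wind",
    "release_puffs",
    "advect_and_grow",
    "concentration_at",
]

_TWO_PI_32 = (2.0 * np.pi) ** 1.5


def _as_vec3(x) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(3)
    if not np.all(np.isfinite(v)):
        raise ValueError("expected a finite 3-vector")
    return v


@dataclass
class WindState:
    """Mean wind plus an OU-type stochastic fluctuation.

    Parameters
    ----------
    mean_velocity : array-like, shape (3,)
        Mean wind vector in m/s.  Default 0.25 m/s along -x.
    turbulence_intensity : float
        Ratio of the per-component fluctuation r.m.s. to the mean speed.
        0 gives a perfectly steady wind ("undisturbed" ~ 0.05, "disturbed"
        ~ 0.3 in the simulated wind-tunnel analogy).
    correlation_time : float
        Relaxation time of the fluctuation, s.
    rng_seed : int
        Seed for the fluctuation noise (ignored if ``rng`` is given).
    """

    mean_velocity: np.ndarray = field(default_factory=lambda: np.array([-0.25, 0.0, 0.0]))
    turbulence_intensity: float = 0.05
    correlation_time: float = 0.5
    rng_seed: int = 0
    fluctuation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rng: np.random.Generator | None = None

    def __post_init__(self) -> None:
        self.mean_velocity = _as_vec3(self.mean_velocity)
        self.fluctuation = _as_vec3(self.fluctuation)
        if self.turbulence_intensity < 0:
            raise ValueError("turbulence_intensity must be >= 0")
        if self.correlation_time <= 0:
            raise ValueError("correlation_time must be > 0")
        if self.rng is None:
            self.rng = np.random.default_rng(self.rng_seed)

    @property
    def instantaneous(self) -> np.ndarray:
        """Instantaneous wind = mean + fluctuation."""
        return self.mean_velocity + self.fluctuation

    @property
    def sigma_u(self) -> float:
        """Stationary per-component fluctuation r.m.s., m/s."""
        return self.turbulence_intensity * float(np.linalg.norm(self.mean_velocity))


def step_wind(state: WindState, dt: float) -> WindState:
    """Advance the wind fluctuation by one OU step of length ``dt``.

    Exact discretisation of the Ornstein-Uhlenbeck process: relaxation by
    exp(-dt/tau) plus Gaussian forcing with the variance that keeps the
    stationary per-component s.d. at ``sigma_u``.  With intensity 0 the
    fluctuation stays exactly zero.  The mean velocity never changes.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if not np.all(np.isfinite(state.fluctuation)):
        raise ValueError("non-finite wind state")
    a = np.exp(-dt / state.correlation_time)
    sigma = state.sigma_u
    if sigma == 0.0:
        new_fluct = a * state.fluctuation
    else:
        noise_sd = sigma * np.sqrt(1.0 - a * a)
        new_fluct = a * state.fluctuation + noise_sd * state.rng.standard_normal(3)
    return replace(state, fluctuation=new_fluct, rng=state.rng)


@dataclass(frozen=True)
class Puff:
    """A single Gaussian odour pocket."""

    centre: np.ndarray
    spread: float  # sigma, m
    strength: float  # Q, odour units (conserved mass)
    birth_time: float  # s


@dataclass
class PlumeConfig:
    source_position: np.ndarray = field(default_factory=lambda: np.array([2.0, 0.0, 0.0]))
    puff_frequency: float = 5.0  # releases per second (paper sweep: 1..9)
    initial_spread: float = 0.05  # m
    growth_rate: float = 1.5e-3  # m^2/s, isotropic (single scalar by design)
    puff_strength: float = 1.0
    domain_bounds: np.ndarray = field(
        default_factory=lambda: np.array([[-0.5, 2.5], [-0.5, 0.5], [-0.5, 0.5]])
    )
    dt: float = 1.0 / 75.0  # s; matches the 75 Hz camera rate
    release_mode: str = "deterministic"  # or "poisson"
    jitter_coefficient: float = 1.0  # scales per-puff random-walk dispersion

    def __post_init__(self) -> None:
        self.source_position = _as_vec3(self.source_position)
        self.domain_bounds = np.asarray(self.domain_bounds, dtype=float).reshape(3, 2)
        if self.puff_frequency <= 0:
            raise ValueError("puff_frequency must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.initial_spread <= 0:
            raise ValueError("initial_spread must be > 0")
        if self.growth_rate < 0:
            raise ValueError("growth_rate must be >= 0")
        if self.release_mode not in ("deterministic", "poisson"):
            raise ValueError("release_mode must be 'deterministic' or 'poisson'")


class PuffPlume:
    """Collection of puffs, stored as flat arrays for speed.

    ``centres`` has shape (m, 3); ``var`` holds sigma^2 so diffusive growth is
    a single addition per step.  Spread is non-decreasing and Q is conserved
    over a puff's lifetime; puffs whose centre leaves ``domain_bounds`` are
    retired.
    """

    def __init__(self, config: PlumeConfig, rng: np.random.Generator | None = None):
        self.config = config
        self.rng = rng if rng is not None else np.random.default_rng(0)
        self.centres = np.empty((0, 3))
        self.var = np.empty(0)  # sigma^2, m^2
        self.strength = np.empty(0)
        self.birth_times = np.empty(0)
        self._next_release: float | None = None  # set on first release call

    # -- views ----------------------------------------------------------
    @property
    def n_puffs(self) -> int:
        return self.centres.shape[0]

    @property
    def puffs(self) -> list[Puff]:
        return [
            Puff(self.centres[i].copy(), float(np.sqrt(self.var[i])),
                 float(self.strength[i]), float(self.birth_times[i]))
            for i in range(self.n_puffs)
        ]

    # -- dynamics -------------------------------------------------------
    def release(self, t: float, dt: float) -> int:
        """Release puffs due in [t, t+dt); returns the number released.

        Deterministic mode releases one puff each 1/frequency seconds;
        Poisson mode draws the count with the same expectation.
        """
        if dt <= 0:
            raise ValueError("dt must be > 0")
        cfg = self.config
        if cfg.release_mode == "deterministic":
            if self._next_release is None:
                self._next_release = t
            n_new = 0
            while self._next_release < t + dt - 1e-12:
                n_new += 1
                self._next_release += 1.0 / cfg.puff_frequency
        else:
            n_new = int(self.rng.poisson(cfg.puff_frequency * dt))
        if n_new:
            self.centres = np.vstack(
                [self.centres, np.tile(cfg.source_position, (n_new, 1))]
            )
            self.var = np.concatenate([self.var, np.full(n_new, cfg.initial_spread**2)])
            self.strength = np.concatenate([self.strength, np.full(n_new, cfg.puff_strength)])
            self.birth_times = np.concatenate([self.birth_times, np.full(n_new, t)])
        return n_new

    def advect_and_grow(self, wind: WindState, dt: float) -> None:
        """Move puffs by wind + per-puff jitter, grow spreads, cull escapees."""
        if dt <= 0:
            raise ValueError("dt must be > 0")
        if self.n_puffs == 0:
            return
        cfg = self.config
        drift = wind.instantaneous * dt
        self.centres = self.centres + drift
        sigma_u = wind.sigma_u * cfg.jitter_coefficient
        if sigma_u > 0:
            # independent random walk per puff; diffusivity sigma_u^2 * tau
            # (Taylor dispersion scale for the unresolved eddies)
            step_sd = sigma_u * np.sqrt(2.0 * dt * wind.correlation_time)
            self.centres = self.centres + step_sd * self.rng.standard_normal(
                self.centres.shape
            )
        self.var = self.var + cfg.growth_rate * dt
        lo, hi = cfg.domain_bounds[:, 0], cfg.domain_bounds[:, 1]
        keep = np.all((self.centres >= lo) & (self.centres <= hi), axis=1)
        if not keep.all():
            self.centres = self.centres[keep]
            self.var = self.var[keep]
            self.strength = self.strength[keep]
            self.birth_times = self.birth_times[keep]

    def concentration_at(self, point) -> float:
        """Gaussian-puff superposition: sum_j Q_j N(point; centre_j, sigma_j^2 I)."""
        p = _as_vec3(point)
        if self.n_puffs == 0:
            return 0.0
        d2 = np.sum((self.centres - p) ** 2, axis=1)
        peak = self.strength / (_TWO_PI_32 * self.var**1.5)
        return float(np.sum(peak * np.exp(-0.5 * d2 / self.var)))


# -- functional wrappers matching the operation contracts ----------------

def release_puffs(plume: PuffPlume, t: float, dt: float) -> PuffPlume:
    plume.release(t, dt)
    return plume


def advect_and_grow(plume: PuffPlume, wind: WindState, dt: float) -> PuffPlume:
    plume.advect_and_grow(wind, dt)
    return plume


def concentration_at(plume: PuffPlume, point) -> float:
    return plume.concentration_at(point)
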