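"""Exact stochastic simulation (Gillespie direct method), empirical
distributions, synthetic observations, and the Monte-Carlo L1 error
prefactor diagnostic.

The L1 error of an empirical distribution built from N exact samples decays
as ``1/sqrt(N)`` with limiting prefactor in the band
``sqrt(2/pi) * (sum_x sqrt(p(x)) -/+ 1)`` — the quantity
:func:`mc_l1_prefactor` computes from a probability table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import engine
from .model import InitialDistribution, ModelError, ReactionNetwork

__all__ = [
    "Trajectory",
    "ObservationSeries",
    "ssa_simulate",
    "ssa_ensemble",
    "empirical_distribution",
    "generate_observations",
    "mc_l1_prefactor",
    "state_key",
]


class SimulationError(RuntimeError):
    pass


def state_key(x: Sequence[float]) -> tuple:
    """Canonical hashable key for a state vector (ints where integral)."""
    out = []
    for v in x:
        fv = float(v)
        out.append(int(fv) if fv.is_integer() else fv)
    return tuple(out)


@dataclass
class Trajectory:
    """An event-sparse, right-continuous piecewise-constant sample path.

    ``times``/``states`` record the post-jump times and states; the state on
    ``[t0, times[0])`` is ``x0``.  Dense views on a time grid are produced by
    :meth:`states_at` without copying the event record.
    """

    t0: float
    t_end: float
    x0: np.ndarray
    times: np.ndarray
    states: np.ndarray
    seed: int
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.times.size and (
            np.any(np.diff(self.times) <= 0)
            or self.times[0] <= self.t0
            or self.times[-1] > self.t_end
        ):
            raise SimulationError("jump times must be strictly increasing within (t0, t_end]")

    @property
    def n_jumps(self) -> int:
        return int(self.times.size)

    def state_at(self, t: float) -> np.ndarray:
        return self.states_at(np.array([t]))[0]

    def states_at(self, times: Sequence[float]) -> np.ndarray:
        """States at the given times (right-continuous)."""
        times = np.asarray(times, dtype=float)
        if times.size and (times.min() < self.t0 or times.max() > self.t_end):
            raise SimulationError("query times outside trajectory span")
        idx = np.searchsorted(self.times, times, side="right")
        full = np.vstack([self.x0[None, :], self.states]) if self.times.size else self.x0[None, :]
        return full[idx]


@dataclass
class ObservationSeries:
    """Noisy readouts ``Y(t_i) = h(X(t_i)) + Sigma W_i`` on a time grid."""

    times: np.ndarray
    values: np.ndarray  # (n_times, n_channels)
    model: object | None = None  # ObservationModel (kept duck-typed)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != self.times.size:
            self.values = self.values.T
        if self.values.shape[0] != self.times.size:
            raise ModelError("observation values/times length mismatch")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ModelError("observation times must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return int(self.values.shape[1])


# ---------------------------------------------------------------------------
# SSA
# ---------------------------------------------------------------------------

_MAX_EVENTS_CAP = 1 << 24


def ssa_simulate(
    network: ReactionNetwork,
    theta: Mapping[str, float] | None,
    x0: Sequence[float] | Mapping[str, float],
    t0: float,
    t_end: float,
    seed: int,
    max_events: int = 1 << 14,
) -> Trajectory:
    """Statistically exact sample path of the reaction network.

    ``theta`` values are taken as given (the grids constrain inference, not
    simulation).  Reproducible for a fixed seed.
    """
    if isinstance(x0, Mapping):
        x0 = np.array([float(x0[name]) for name in network.names])
    x0 = np.asarray(x0, dtype=float)
    enc = engine.compile_network(network, theta)
    cap = max_events
    while True:
        times, states, m, status = engine._ssa_kernel(
            x0, float(t0), float(t_end), np.uint32(seed), cap, *enc.kernel_args()
        )
        if status == 0:
            return Trajectory(
                t0=float(t0),
                t_end=float(t_end),
                x0=x0.copy(),
                times=times[:m].copy(),
                states=states[:m].copy(),
                seed=int(seed),
                names=network.names,
            )
        if status == -2:
            raise SimulationError("propensity evaluated negative or non-finite during SSA")
        cap *= 4
        if cap > _MAX_EVENTS_CAP:
            raise SimulationError("SSA event count exceeded the buffer cap")


def _trajectory_seeds(seed: int, N: int) -> list[np.random.Generator]:
    """One independent RNG stream per trajectory via counter-based spawning,
    so ensembles are reproducible independent of scheduling."""
    return [np.random.default_rng(child) for child in np.random.SeedSequence(seed).spawn(N)]


def ssa_ensemble(
    network: ReactionNetwork,
    theta: Mapping[str, float] | None,
    init: InitialDistribution | Sequence[float],
    t0: float,
    t_end: float,
    N: int,
    seed: int,
) -> list[Trajectory]:
    """N independent SSA runs; initial states drawn from ``init`` if it is a
    distribution, else fixed."""
    out = []
    for rng in _trajectory_seeds(seed, N):
        if isinstance(init, InitialDistribution):
            x0 = init.sample_state(network, rng)
        else:
            x0 = np.asarray(init, dtype=float)
        kernel_seed = int(rng.integers(0, 2**31 - 1))
        out.append(ssa_simulate(network, theta, x0, t0, t_end, kernel_seed))
    return out


# ---------------------------------------------------------------------------
# empirical distributions and the MC error-prefactor diagnostic
# ---------------------------------------------------------------------------


def empirical_distribution(trajectories: Iterable[Trajectory], t: float) -> dict[tuple, float]:
    """Sparse empirical probability table of the ensemble at time ``t``."""
    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("empty trajectory list")
    table: dict[tuple, float] = {}
    w = 1.0 / len(trajectories)
    for traj in trajectories:
        key = state_key(traj.state_at(t))
        table[key] = table.get(key, 0.0) + w
    return table


def generate_observations(
    trajectory: Trajectory,
    obs_model,
    times: Sequence[float],
    seed: int,
) -> ObservationSeries:
    """Read out ``h(X(t_i))`` through the observation model with additive
    Gaussian channel noise."""
    times = np.asarray(times, dtype=float)
    states = trajectory.states_at(times)
    H = obs_model.h_matrix(states, trajectory.names)
    sigma = np.asarray(obs_model.sigma, dtype=float)
    if np.any(sigma < 0):
        raise ModelError("negative observation noise intensity")
    rng = np.random.default_rng(seed)
    Y = H + rng.standard_normal(H.shape) * sigma[None, :]
    return ObservationSeries(times=times, values=Y, model=obs_model)


def mc_l1_prefactor(distribution) -> tuple[float, float, float]:
    """Pre-convergence-rate factor band for the Monte-Carlo L1 error.

    Returns ``(center, lower, upper)`` with
    ``center = sqrt(2/pi) * sum_x sqrt(p(x))`` and the band half-width
    ``sqrt(2/pi)``.  For a uniform law on S states the sum equals
    ``sqrt(S)``; for a product law it factorizes over the marginals.
    """
    if isinstance(distribution, Mapping):
        p = np.array(list(distribution.values()), dtype=float)
    else:
        p = np.asarray(distribution, dtype=float).ravel()
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("input is not a probability table (tolerance 1e-9)")
    c = math.sqrt(2.0 / math.pi)
    s = float(np.sqrt(p).sum())
    return c * s, c * (s - 1.0), c * (s + 1.0)
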