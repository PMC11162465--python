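"""Stochastic filtering from time-course observations.

Observations follow ``Y(t_i) = h(X(t_i)) + Sigma W_i`` with iid standard
Gaussian ``W_i``.  The posterior recursion alternates a prediction step
(solving the CME from the current posterior) and a Bayes correction by the
likelihood.  Three solvers share this recursion:

* :func:`exact_fsp_filter` — FSP prediction on the full truncation (the
  reference filter for small systems);
* :func:`bootstrap_pf` — SSA proposal particles with Gaussian weighting and
  systematic resampling;
* :func:`rb_particle_filter` — the Rao-Blackwellized particle filter, whose
  particles carry a leader state plus follower filters; the prediction step
  is the RB-CME solver and the correction marginalizes the likelihood over
  each particle's follower filters (exact per subsystem under C3).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .decompose import Decomposition
from .filtered_cme import (
    FilteredFspEngine,
    FilterJumpImpossible,
    FilterMassLost,
    extract_leader_path,
)
from .fsp import TruncatedStateSpace, fsp_solve, initial_vector
from .model import InitialDistribution, ModelError, ReactionNetwork
from .rb_solver import MarginalTable, RbEstimate, dense_from_empirical, dense_joint, marginalize
from .simulate import ObservationSeries, ssa_simulate

__all__ = [
    "Channel",
    "ObservationModel",
    "FilterPosterior",
    "gaussian_likelihood",
    "exact_fsp_filter",
    "bootstrap_pf",
    "rb_particle_filter",
    "systematic_resample",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


class FilterCollapse(RuntimeError):
    """Every particle weight vanished at an observation."""


# ---------------------------------------------------------------------------
# observation models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Channel:
    """One readout channel: identity, thresholded identity (the readout is
    zero unless the count exceeds the threshold), or a linear combination
    over species."""

    kind: str  # "identity" | "threshold" | "linear"
    species: str | None = None
    threshold: float = 0.0
    coeffs: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("identity", "threshold", "linear"):
            raise ModelError(f"unknown channel kind {self.kind!r}")
        if self.kind in ("identity", "threshold") and self.species is None:
            raise ModelError("identity/threshold channel needs a species")
        if self.kind == "linear" and not self.coeffs:
            raise ModelError("linear channel needs coefficients")

    def depends_on(self) -> set[str]:
        if self.kind == "linear":
            return {n for n, _c in self.coeffs}
        return {self.species}

    def h_values(self, X: np.ndarray, names: Sequence[str]) -> np.ndarray:
        """Ideal readout for a batch of states ``X`` of shape ``(m, n)``."""
        names = list(names)
        if self.kind == "linear":
            out = np.zeros(X.shape[0])
            for n, c in self.coeffs:
                out += c * X[:, names.index(n)]
            return out
        x = X[:, names.index(self.species)]
        if self.kind == "identity":
            return x.astype(float)
        return np.where(x > self.threshold, x, 0.0).astype(float)


@dataclass(frozen=True)
class ObservationModel:
    """Channels plus the diagonal noise intensities Sigma.

    A sigma entry may be the name of a parameter pseudo-species instead of
    a number, in which case the noise intensity is inferred alongside the
    other parameters (it then counts as a dependency of its channel for
    condition C3)."""

    channels: tuple[Channel, ...]
    sigma: tuple[float | str, ...]

    def __post_init__(self) -> None:
        if len(self.channels) != len(self.sigma):
            raise ModelError("one sigma per channel required")
        if any(not isinstance(s, str) and s < 0 for s in self.sigma):
            raise ModelError("negative observation noise intensity")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channel_deps(self, c: int) -> set[str]:
        deps = set(self.channels[c].depends_on())
        if isinstance(self.sigma[c], str):
            deps.add(self.sigma[c])
        return deps

    def sigma_values(self, c: int, X: np.ndarray, names: Sequence[str]):
        """Noise intensity per state row (scalar when fixed)."""
        s = self.sigma[c]
        if isinstance(s, str):
            return np.asarray(X, dtype=float)[:, list(names).index(s)]
        return float(s)

    def h_matrix(self, X: np.ndarray, names: Sequence[str]) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.stack([ch.h_values(X, names) for ch in self.channels], axis=1)


def _channel_loglik(y: float, h: np.ndarray, sigma) -> np.ndarray:
    """Log-likelihood of observation ``y`` for candidate readouts ``h``;
    ``sigma`` may vary per state.  A zero-noise entry matches exactly with
    unit mass."""
    h = np.asarray(h, dtype=float)
    if np.ndim(sigma) == 0 and sigma > 0.0:
        s = float(sigma)
        return -0.5 * ((y - h) / s) ** 2 - (math.log(s) + _LOG_SQRT_2PI)
    sig = np.broadcast_to(np.asarray(sigma, dtype=float), h.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        gauss = -0.5 * ((y - h) / sig) ** 2 - np.log(sig) - _LOG_SQRT_2PI
    exact = np.where(np.isclose(h, y, atol=1e-9), 0.0, -np.inf)
    return np.where(sig == 0.0, exact, gauss)


def gaussian_likelihood(
    obs_model: ObservationModel,
    y: Sequence[float],
    x: Sequence[float],
    names: Sequence[str],
) -> float:
    """Likelihood ``L(y | x)``: a product of per-channel normal densities
    centered at ``h(x)`` (exact matching for zero-noise channels)."""
    y = np.atleast_1d(np.asarray(y, dtype=float))
    X = np.asarray(x, dtype=float)[None, :]
    H = obs_model.h_matrix(X, names)[0]
    total = 0.0
    for c in range(obs_model.n_channels):
        sig = obs_model.sigma_values(c, X, names)
        total += float(np.atleast_1d(_channel_loglik(y[c], np.array([H[c]]), sig))[0])
    return math.exp(total) if np.isfinite(total) else 0.0


# ---------------------------------------------------------------------------
# posterior container
# ---------------------------------------------------------------------------


@dataclass
class FilterPosterior:
    """Per-observation-time posteriors plus the log marginal likelihood.

    ``snapshots[k]`` is a dense vector (exact filter), a ``(states,
    weights)`` pair (bootstrap PF), or an :class:`RbEstimate` (RB-PF).
    """

    method: str
    network: ReactionNetwork
    times: np.ndarray
    snapshots: list
    log_marginal_steps: np.ndarray
    space: TruncatedStateSpace | None = None
    decomposition: Decomposition | None = None

    @property
    def log_marginal_likelihood(self) -> float:
        return float(np.sum(self.log_marginal_steps))

    def dense(self, k: int) -> tuple[np.ndarray, float]:
        """Posterior at step ``k`` as a dense table on the truncation plus
        outside mass."""
        snap = self.snapshots[k]
        if self.method == "exact":
            return snap.reshape(self.space.sizes), 0.0
        if self.method == "pf":
            states, weights = snap
            table: dict[tuple, float] = {}
            from .simulate import state_key

            for x, w in zip(states, weights):
                key = state_key(x)
                table[key] = table.get(key, 0.0) + float(w)
            values = [self.network.species_by_name(n).values for n in self.network.names]
            return dense_from_empirical(table, values)
        est = snap
        m = dense_joint(est)
        return m.table, m.outside

    def marginal(self, k: int, components: Sequence[str]) -> MarginalTable:
        components = tuple(components)
        if self.method == "rbpf":
            return marginalize(self.snapshots[k], components)
        dense, outside = self.dense(k)
        names = self.network.names
        keep = tuple(names.index(n) for n in components)
        drop = tuple(a for a in range(len(names)) if a not in keep)
        tab = dense.sum(axis=drop) if drop else dense
        tab = np.transpose(tab, np.argsort(np.argsort(keep)))
        values = tuple(tuple(self.network.species_by_name(n).values) for n in components)
        return MarginalTable(names=components, values=values, table=tab, outside=outside)

    def mean_and_sd(self, k: int, component: str) -> tuple[float, float]:
        m = self.marginal(k, (component,))
        v = np.asarray(m.values[0])
        p = m.table / max(m.table.sum(), 1e-300)
        mu = float(v @ p)
        var = float((v - mu) ** 2 @ p)
        return mu, math.sqrt(max(var, 0.0))


# ---------------------------------------------------------------------------
# exact filter
# ---------------------------------------------------------------------------


def exact_fsp_filter(
    network: ReactionNetwork,
    space: TruncatedStateSpace,
    obs_series: ObservationSeries,
    theta: Mapping[str, float] | None = None,
    init: InitialDistribution | np.ndarray | None = None,
    method: str = "uniformization",
) -> FilterPosterior:
    """Reference filter: FSP prediction on the full truncation alternated
    with pointwise Bayes corrections."""
    obs_model: ObservationModel = obs_series.model
    if obs_model is None:
        raise ModelError("observation series carries no observation model")
    p = initial_vector(network, space, init)
    all_states = space.all_states()
    H = obs_model.h_matrix(all_states, space.names)
    SIG = [obs_model.sigma_values(c, all_states, space.names) for c in range(obs_model.n_channels)]
    t_prev = 0.0
    snaps, log_steps = [], []
    for k, t_i in enumerate(obs_series.times):
        if t_i > t_prev:
            sol = fsp_solve(network, space, p, t_i - t_prev, theta, method=method)
            p = sol.p
            s = p.sum()
            if s <= 0:
                raise FilterCollapse("all mass left the truncation during prediction")
            p = p / s
        logL = np.zeros(space.size)
        for c in range(obs_model.n_channels):
            logL += _channel_loglik(obs_series.values[k, c], H[:, c], SIG[c])
        w = p * np.exp(logL - np.max(logL[np.isfinite(logL)], initial=0.0))
        mass = w.sum()
        if mass <= 0:
            raise FilterCollapse(f"zero posterior mass at observation {k}")
        log_steps.append(float(logsumexp(logL, b=p)))
        p = w / mass
        snaps.append(p.copy())
        t_prev = float(t_i)
    return FilterPosterior(
        method="exact",
        network=network,
        times=obs_series.times.copy(),
        snapshots=snaps,
        log_marginal_steps=np.asarray(log_steps),
        space=space,
    )


# ---------------------------------------------------------------------------
# bootstrap particle filter
# ---------------------------------------------------------------------------


def systematic_resample(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Systematic resampling: lowest-variance standard scheme; ties resolve
    by particle index, deterministic for a fixed seed."""
    N = weights.size
    positions = (rng.random() + np.arange(N)) / N
    return np.searchsorted(np.cumsum(weights), positions).clip(0, N - 1)


def _normalize_log_weights(logw: np.ndarray) -> tuple[np.ndarray, float]:
    m = np.max(logw)
    if not np.isfinite(m):
        raise FilterCollapse("all particle weights vanished")
    w = np.exp(logw - m)
    total = w.sum()
    return w / total, float(m + np.log(total))


def bootstrap_pf(
    network: ReactionNetwork,
    obs_series: ObservationSeries,
    N: int,
    seed: int,
    theta: Mapping[str, float] | None = None,
    init: InitialDistribution | None = None,
) -> FilterPosterior:
    """Bootstrap particle filter: SSA proposal between observations,
    Gaussian weighting, systematic resampling when ESS < N/2."""
    if N < 2:
        raise ValueError("at least two particles required")
    obs_model: ObservationModel = obs_series.model
    init = init if init is not None else network.initial
    rng = np.random.default_rng(seed)
    states = np.stack([init.sample_state(network, rng) for _ in range(N)])
    logw = np.zeros(N)
    t_prev = 0.0
    names = network.names
    snaps, log_steps = [], []
    for k, t_i in enumerate(obs_series.times):
        if t_i > t_prev:
            for p_i in range(N):
                traj = ssa_simulate(
                    network, theta, states[p_i], t_prev, t_i,
                    int(rng.integers(0, 2**31 - 1)),
                )
                states[p_i] = traj.state_at(t_i)
        H = obs_model.h_matrix(states, names)
        step = np.zeros(N)
        for c in range(obs_model.n_channels):
            step += _channel_loglik(
                obs_series.values[k, c], H[:, c], obs_model.sigma_values(c, states, names)
            )
        if not np.any(np.isfinite(step)):
            warnings.warn("weight collapse; tempering the likelihood once", stacklevel=2)
            step = 0.5 * step
        w_prev, _ = _normalize_log_weights(logw)
        log_steps.append(float(logsumexp(step, b=w_prev)))
        logw = logw + step
        weights, _ = _normalize_log_weights(logw)
        snaps.append((states.copy(), weights.copy()))
        if 1.0 / np.sum(weights**2) < N / 2:
            idx = systematic_resample(weights, rng)
            states = states[idx]
            logw = np.zeros(N)
        t_prev = float(t_i)
    return FilterPosterior(
        method="pf",
        network=network,
        times=obs_series.times.copy(),
        snapshots=snaps,
        log_marginal_steps=np.asarray(log_steps),
    )


# ---------------------------------------------------------------------------
# Rao-Blackwellized particle filter
# ---------------------------------------------------------------------------


def rb_particle_filter(
    network: ReactionNetwork,
    decomposition: Decomposition,
    obs_series: ObservationSeries,
    N: int,
    seed: int,
    theta: Mapping[str, float] | None = None,
    init: InitialDistribution | None = None,
    engine: FilteredFspEngine | None = None,
    keep_history: bool = True,
) -> FilterPosterior:
    """The RB-PF: particles carry a leader state plus follower filters.

    Between observations each particle draws one follower configuration
    from its conditionals, simulates the whole system by SSA, keeps the
    leader path (an exact draw from the leader's conditional marginal), and
    rebuilds the follower filters from its previous conditionals along that
    path.  The weight update marginalizes each channel's likelihood over
    the touched follower filter (exact under C3), which simultaneously
    Bayes-corrects that filter.

    With ``keep_history=False`` only the final-time posterior is retained
    (identification over long series needs just the last snapshot, and a
    full history of particle filters can run to gigabytes).
    """
    obs_model: ObservationModel = obs_series.model
    if obs_model is None:
        raise ModelError("observation series carries no observation model")
    init = init if init is not None else network.initial
    eng = engine or FilteredFspEngine(network, decomposition, theta)
    rng = np.random.default_rng(seed)
    sub_of = {n: i for i, sub in enumerate(decomposition.subsystems) for n in sub}
    chan_sub: list[int | None] = []
    for c in range(obs_model.n_channels):
        subs = {sub_of[n] for n in obs_model.channel_deps(c) if n in sub_of}
        if len(subs) > 1:
            raise ModelError("observation channel touches several subsystems (C3)")
        chan_sub.append(next(iter(subs)) if subs else None)

    lead_names = decomposition.leaders
    leader_states = np.stack(
        [
            np.array([init.marginal_for(n).sample(rng) for n in lead_names])
            for _ in range(N)
        ]
    )
    filters = [eng.initial_filters(init) for _ in range(N)]
    logw = np.zeros(N)
    t_prev = 0.0
    snaps, log_steps = [], []
    hvec_cache: dict = {}

    def channel_h_on_sub(c: int, i: int, lead: np.ndarray):
        ch = obs_model.channels[c]
        dep_lead = sorted(obs_model.channel_deps(c) & set(lead_names))
        key = (c, i, tuple(lead[lead_names.index(n)] for n in dep_lead))
        if key not in hvec_cache:
            X = eng.assembled_states(i, lead)
            hvec_cache[key] = (
                ch.h_values(X, network.names),
                obs_model.sigma_values(c, X, network.names),
            )
        return hvec_cache[key]

    for k, t_i in enumerate(obs_series.times):
        # --- prediction: advance each particle's leader path and filters
        if t_i > t_prev:
            for p_i in range(N):
                if not np.isfinite(logw[p_i]):
                    continue
                x = np.zeros(network.n)
                x[eng.leader_idx] = leader_states[p_i]
                for i in range(len(eng.spaces)):
                    cdf = np.cumsum(filters[p_i][i].probs)
                    z = int(np.searchsorted(cdf, rng.random() * cdf[-1]))
                    x[eng.sub_idx[i]] = eng._sub_states[i][min(z, cdf.size - 1)]
                traj = ssa_simulate(
                    network, theta, x, t_prev, t_i, int(rng.integers(0, 2**31 - 1))
                )
                path = extract_leader_path(traj, network, decomposition)
                try:
                    eng.advance(filters[p_i], path, [])
                    leader_states[p_i] = path.final_state()
                except (FilterJumpImpossible, FilterMassLost):
                    logw[p_i] = -np.inf
        # --- correction
        saved = [[f.copy() for f in fs] for fs in filters]
        for temper in (1.0, 0.5):
            step = np.zeros(N)
            for p_i in range(N):
                if not np.isfinite(logw[p_i]):
                    step[p_i] = -np.inf
                    continue
                lead = leader_states[p_i]
                for c in range(obs_model.n_channels):
                    y = obs_series.values[k, c]
                    i = chan_sub[c]
                    if i is None:
                        x = np.zeros(network.n)
                        x[eng.leader_idx] = lead
                        h = obs_model.channels[c].h_values(x[None, :], network.names)[0]
                        ll = temper * np.atleast_1d(
                            _channel_loglik(y, np.array([h]), obs_model.sigma[c])
                        )[0]
                        step[p_i] += ll
                        if not np.isfinite(step[p_i]):
                            break
                    else:
                        hvec, sigvec = channel_h_on_sub(c, i, lead)
                        Lvec = np.exp(temper * _channel_loglik(y, hvec, sigvec))
                        f = filters[p_i][i]
                        mass = float(f.probs @ Lvec)
                        if mass <= 0.0:
                            step[p_i] = -np.inf
                            break
                        f.probs = f.probs * Lvec / mass
                        f.log_norm += math.log(mass)
                        step[p_i] += math.log(mass)
            if np.any(np.isfinite(logw + step)):
                break
            warnings.warn("RB-PF weight collapse; tempering the likelihood once", stacklevel=2)
            filters = [[f.copy() for f in fs] for fs in saved]
        w_prev, _ = _normalize_log_weights(logw)
        finite = np.isfinite(step)
        log_steps.append(
            float(logsumexp(step[finite], b=w_prev[finite])) if np.any(finite) else -np.inf
        )
        logw = logw + step
        weights, _ = _normalize_log_weights(logw)
        last = k == len(obs_series.times) - 1
        if keep_history or last:
            est = RbEstimate(
                network=network,
                decomposition=decomposition,
                t=float(t_i),
                leader_states=leader_states.copy(),
                filters=[[f.copy() for f in fs] for fs in filters],
                weights=weights.copy(),
                N=N,
                engine=eng,
            )
            snaps.append(est)
        if 1.0 / np.sum(weights**2) < N / 2:
            idx = systematic_resample(weights, rng)
            leader_states = leader_states[idx]
            filters = [[f.copy() for f in filters[j]] for j in idx]
            logw = np.zeros(N)
        t_prev = float(t_i)
    return FilterPosterior(
        method="rbpf",
        network=network,
        times=obs_series.times.copy(),
        snapshots=snaps,
        log_marginal_steps=np.asarray(log_steps),
        decomposition=decomposition,
    )
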