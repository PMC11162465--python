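"""Finite state projection: truncated CME integration with a sink-mass error
bound, and stationary distributions by long-horizon integration.

The CME restricted to a finite truncation, augmented with a single absorbing
sink state collecting all outflow, yields a solvable linear ODE system whose
accumulated sink mass upper-bounds the L1 truncation error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp

from . import engine
from .model import InitialDistribution, ModelError, ReactionNetwork

__all__ = [
    "TruncatedStateSpace",
    "FspSolution",
    "truncated_space",
    "build_generator",
    "fsp_solve",
    "stationary_distribution",
]


class FspError(RuntimeError):
    pass


@dataclass(frozen=True)
class TruncatedStateSpace:
    """Product truncation with a mixed-radix state<->index bijection."""

    names: tuple[str, ...]
    component_values: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "component_values",
            tuple(tuple(float(v) for v in vals) for vals in self.component_values),
        )

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(v) for v in self.component_values)

    @property
    def size(self) -> int:
        out = 1
        for s in self.sizes:
            out *= s
        return out

    @property
    def n(self) -> int:
        return len(self.names)

    def _strides(self) -> np.ndarray:
        sizes = self.sizes
        strides = np.ones(len(sizes), dtype=np.int64)
        for i in range(len(sizes) - 2, -1, -1):
            strides[i] = strides[i + 1] * sizes[i + 1]
        return strides

    def all_states(self) -> np.ndarray:
        """All states as a ``(size, n)`` array in index order (C order,
        last component fastest)."""
        grids = np.meshgrid(*[np.asarray(v) for v in self.component_values], indexing="ij")
        return np.stack([g.ravel() for g in grids], axis=1)

    def positions(self, component: int, values: np.ndarray) -> np.ndarray:
        """Positions of values within one component's list; -1 if absent."""
        vals = np.asarray(self.component_values[component])
        pos = np.searchsorted(vals, values)
        pos_c = np.clip(pos, 0, len(vals) - 1)
        ok = np.isclose(vals[pos_c], values, rtol=0.0, atol=1e-9)
        return np.where(ok, pos_c, -1)

    def index_of(self, state: Sequence[float]) -> int:
        strides = self._strides()
        idx = 0
        for i, v in enumerate(state):
            pos = self.positions(i, np.array([float(v)]))[0]
            if pos < 0:
                raise FspError(f"state {tuple(state)} outside truncation")
            idx += pos * strides[i]
        return int(idx)

    def state_of(self, index: int) -> np.ndarray:
        strides = self._strides()
        out = np.empty(self.n)
        rem = int(index)
        for i in range(self.n):
            pos, rem = divmod(rem, int(strides[i]))
            out[i] = self.component_values[i][pos]
        return out


def truncated_space(
    network: ReactionNetwork,
    subset: Sequence[str] | None = None,
    overrides: Mapping[str, Sequence[float]] | None = None,
) -> TruncatedStateSpace:
    """Truncated space over ``subset`` (default: all species) using each
    species' declared admissible values unless overridden."""
    overrides = dict(overrides or {})
    names = tuple(subset) if subset is not None else network.names
    values = []
    for name in names:
        if name in overrides:
            values.append(tuple(float(v) for v in overrides[name]))
        else:
            values.append(tuple(network.species_by_name(name).values))
    return TruncatedStateSpace(names=names, component_values=tuple(values))


@dataclass
class FspSolution:
    """Probability vector on the truncation plus accumulated sink mass."""

    space: TruncatedStateSpace
    p: np.ndarray
    sink_mass: float
    t: float

    def __post_init__(self) -> None:
        total = float(self.p.sum()) + self.sink_mass
        if np.any(self.p < -1e-10) or not (1 - 1e-8 <= total <= 1 + 1e-8):
            raise FspError(f"FSP solution mass {total} violates conservation")
        self.p = np.clip(self.p, 0.0, None)


# ---------------------------------------------------------------------------
# generator assembly
# ---------------------------------------------------------------------------


def build_generator(
    network: ReactionNetwork,
    space: TruncatedStateSpace,
    theta: Mapping[str, float] | None = None,
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Sparse CME generator on the truncation.

    Returns ``(A, sink_rates)`` where ``dp/dt = A p`` and
    ``d(sink)/dt = sink_rates . p``; each column of ``A`` sums to
    ``-sink_rates`` (probability conservation including the sink).
    Propensities are evaluated with components outside ``space.names`` set
    to zero — valid whenever the subnetwork is self-contained (always the
    case for full-network spaces).
    """
    enc = engine.compile_network(network, theta)
    comp_idx = np.array([network.index_of(n) for n in space.names], dtype=np.int64)
    S = space.size
    states_sub = space.all_states()
    X = np.zeros((S, network.n))
    X[:, comp_idx] = states_sub
    lam = engine.eval_propensities(enc, X)  # (S, r)
    if not np.all(np.isfinite(lam)):
        raise FspError("infinite propensity on the truncation")

    strides = space._strides()
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    data: list[np.ndarray] = []
    diag = np.zeros(S)
    sink = np.zeros(S)
    src_idx = np.arange(S, dtype=np.int64)

    zeta = network.zeta[:, comp_idx]  # net change restricted to the space
    zeta_out = np.delete(network.zeta, comp_idx, axis=1)
    for j in range(network.r):
        lj = lam[:, j]
        active = lj > 0
        if not np.any(active):
            continue
        if np.any(zeta_out[j] != 0):
            # reaction moves components outside this space: treat as outflow
            # to the sink (mass leaves the projected subsystem)
            if np.all(zeta[j] == 0):
                continue  # no change within the space and none tracked here
        target = np.zeros(S, dtype=np.int64)
        valid = active.copy()
        if np.all(zeta[j] == 0):
            continue  # no state change within this space
        for i in np.nonzero(zeta[j])[0]:
            newvals = states_sub[:, i] + zeta[j, i]
            pos = space.positions(i, newvals)
            valid &= pos >= 0
            target += np.where(pos >= 0, pos, 0) * strides[i]
        for i in np.nonzero(zeta[j] == 0)[0]:
            pos = space.positions(i, states_sub[:, i])
            target += pos * strides[i]
        inside = valid & active
        outside = active & ~valid
        rows.append(target[inside])
        cols.append(src_idx[inside])
        data.append(lj[inside])
        np.subtract.at(diag, src_idx[active], lj[active])
        np.add.at(sink, src_idx[outside], lj[outside])

    rows.append(src_idx)
    cols.append(src_idx)
    data.append(diag)
    A = sp.csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))), shape=(S, S)
    )
    return A, sink


def _with_sink(A: sp.csr_matrix, sink: np.ndarray) -> sp.csr_matrix:
    S = A.shape[0]
    Afull = sp.lil_matrix((S + 1, S + 1))
    Afull[:S, :S] = A
    Afull[S, :S] = sink
    return Afull.tocsr()


def fsp_solve(
    network: ReactionNetwork,
    space: TruncatedStateSpace,
    p0: np.ndarray | InitialDistribution,
    t: float,
    theta: Mapping[str, float] | None = None,
    method: str = "ode",
    rtol: float = 1e-8,
    atol: float = 1e-12,
    sink_bound: float | None = None,
) -> FspSolution:
    """Integrate the truncated CME to time ``t``.

    The L1 distance to the untruncated solution is bounded by the returned
    ``sink_mass``.  ``method`` is ``"ode"`` (adaptive BDF on the sparse
    generator) or ``"uniformization"`` (exact matrix-exponential action,
    preferable for stiff short-horizon propagation).
    """
    p0 = initial_vector(network, space, p0)
    if t <= 0:
        return FspSolution(space=space, p=p0.copy(), sink_mass=0.0, t=0.0)
    A, sink = build_generator(network, space, theta)
    Afull = _with_sink(A, sink)
    y0 = np.concatenate([p0, [0.0]])
    if method == "uniformization":
        y = engine.expm_action(Afull, y0, t)
    elif method == "ode":
        res = solve_ivp(
            lambda _t, y: Afull @ y,
            (0.0, float(t)),
            y0,
            method="BDF",
            jac=Afull,
            rtol=rtol,
            atol=atol,
        )
        if not res.success:
            raise FspError(f"CME integration failed: {res.message}")
        y = res.y[:, -1]
    else:
        raise ValueError(f"unknown method {method!r}")
    sol = FspSolution(space=space, p=y[:-1], sink_mass=max(float(y[-1]), 0.0), t=float(t))
    if sink_bound is not None and sol.sink_mass > sink_bound:
        warnings.warn(
            f"sink mass {sol.sink_mass:.3g} exceeds requested bound {sink_bound:.3g}",
            stacklevel=2,
        )
    return sol


def initial_vector(
    network: ReactionNetwork,
    space: TruncatedStateSpace,
    p0: np.ndarray | InitialDistribution | None,
) -> np.ndarray:
    """Dense probability vector on the truncation for an initial law."""
    if p0 is None:
        p0 = network.initial
    if isinstance(p0, InitialDistribution):
        if p0.marginals is not None:
            vec = np.ones(1)
            for i, name in enumerate(space.names):
                marg = p0.marginal_for(name).pmf_on(np.asarray(space.component_values[i]))
                vec = np.kron(vec, marg)
            return vec
        vec = np.zeros(space.size)
        for key, prob in p0.table.items():
            vec[space.index_of(key)] += prob
        return vec / vec.sum()
    vec = np.asarray(p0, dtype=float)
    if vec.shape != (space.size,):
        raise ModelError("initial vector length does not match the truncation")
    if np.any(vec < 0) or abs(vec.sum() - 1.0) > 1e-8:
        raise ModelError("initial vector is not a probability vector")
    return vec


def stationary_distribution(
    network: ReactionNetwork,
    space: TruncatedStateSpace,
    theta: Mapping[str, float] | None = None,
    tol: float = 1e-9,
    max_horizon: float = 1e6,
    p0: np.ndarray | InitialDistribution | None = None,
) -> np.ndarray:
    """Stationary law on the truncation by integrating to a large time point.

    Integration proceeds in doubling steps (renormalizing sink leakage away)
    until the residual ``||A p||_1`` drops below ``tol`` per unit time, or
    plateaus at the truncation-leak floor, or the horizon is exhausted.
    """
    A, sink = build_generator(network, space, theta)
    if p0 is None and network.initial is None:
        p = np.full(space.size, 1.0 / space.size)
    else:
        p = initial_vector(network, space, p0)
    leak = float(sink @ np.full(space.size, 1.0 / space.size))
    t, dt = 0.0, 1.0
    prev_res = np.inf
    while t < max_horizon:
        p = engine.expm_action(A, p, dt)
        total = p.sum()
        if total <= 0:
            raise FspError("all probability mass left the truncation")
        p = p / total
        t += dt
        res = float(np.abs(A @ p).sum())
        floor = float(sink @ p)
        if res < tol or res <= 2.0 * floor:
            return p
        if res > prev_res * (1 - 1e-12) and res < 1e-6:
            warnings.warn("stationary residual plateaued above tol; accepting", stacklevel=2)
            return p
        prev_res = res
        dt = min(dt * 2.0, max_horizon - t) if t + dt <= max_horizon else max_horizon - t
        if dt <= 0:
            break
    raise FspError(f"stationary integration did not converge within horizon (residual {prev_res:.3g})")
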