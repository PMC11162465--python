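"""The filtered CME: conditional distributions of follower subsystems given
a leader-system trajectory, solved by the filtered finite state projection.

Between leader jumps each subsystem's conditional law ``pi_{Z_i|X}``
evolves by (i) the subsystem's internal CME at the frozen leader state and
(ii) an exponential reweighting ``exp(-int Lambda(z_i) ds)`` with
``Lambda(z_i)`` the total rate of leader-changing reactions whose propensity
depends on ``z_i`` — the Bayesian conditioning on "no leader jump occurred".
At an observed leader jump with net change ``Delta`` the filter receives the
Bayes update

    pi'(z) \propto sum_{j: zeta_j^X = Delta} lambda_j(x-, z - zeta_j^Z) pi(z - zeta_j^Z),

renormalized; subsystems untouched by the matching reactions are unchanged.
Both operators are linear, so the survival/jump normalizers accumulate into
a per-filter log-normalizer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from . import engine as _eng
from .decompose import Decomposition
from .fsp import TruncatedStateSpace
from .model import InitialDistribution, ModelError, ReactionNetwork
from .simulate import Trajectory

__all__ = [
    "LeaderTrajectory",
    "FollowerFilter",
    "FilteredFspEngine",
    "FilterJumpImpossible",
    "extract_leader_path",
    "filtered_propagate",
    "filtered_jump_update",
    "filter_along_trajectory",
]

_MASS_FLOOR = 1e-300


class FilterJumpImpossible(RuntimeError):
    """The observed leader jump has zero probability under the filter.

    Recoverable: ensemble callers zero the affected particle's weight."""


class FilterMassLost(RuntimeError):
    """All filter mass annihilated during propagation."""


@dataclass
class LeaderTrajectory:
    """A piecewise-constant leader path with per-jump net changes."""

    t0: float
    t_end: float
    names: tuple[str, ...]
    x0: np.ndarray
    times: np.ndarray
    states: np.ndarray  # leader state after each jump
    deltas: np.ndarray  # leader net change at each jump

    @property
    def n_jumps(self) -> int:
        return int(self.times.size)

    def state_before(self, k: int) -> np.ndarray:
        """Leader state on the segment ending at jump ``k``."""
        return self.x0 if k == 0 else self.states[k - 1]

    def final_state(self) -> np.ndarray:
        return self.x0 if self.n_jumps == 0 else self.states[-1]


def extract_leader_path(
    traj: Trajectory, network: ReactionNetwork, decomposition: Decomposition
) -> LeaderTrajectory:
    """Project a full trajectory onto the leader components, keeping only
    the jumps that change the leader state."""
    idx = np.array([network.index_of(n) for n in decomposition.leaders], dtype=np.int64)
    x0 = traj.x0[idx]
    if traj.n_jumps == 0:
        empty = np.empty((0, idx.size))
        return LeaderTrajectory(
            traj.t0, traj.t_end, decomposition.leaders, x0, np.empty(0), empty, empty.copy()
        )
    lead = traj.states[:, idx]
    prev = np.vstack([x0[None, :], lead[:-1]])
    changed = np.any(lead != prev, axis=1)
    return LeaderTrajectory(
        t0=traj.t0,
        t_end=traj.t_end,
        names=decomposition.leaders,
        x0=x0,
        times=traj.times[changed].copy(),
        states=lead[changed].copy(),
        deltas=(lead - prev)[changed].copy(),
    )


@dataclass
class FollowerFilter:
    """Conditional distribution of one follower subsystem."""

    subsystem: int
    probs: np.ndarray
    t: float
    log_norm: float = 0.0

    def copy(self) -> "FollowerFilter":
        return FollowerFilter(self.subsystem, self.probs.copy(), self.t, self.log_norm)


# ---------------------------------------------------------------------------
# the filtered-FSP engine
# ---------------------------------------------------------------------------


class FilteredFspEngine:
    """Precomputed machinery for advancing follower filters along a leader
    path: per-subsystem truncations, reaction classification, and caches of
    the (leader-state dependent) filtered generators and jump matrices."""

    def __init__(
        self,
        network: ReactionNetwork,
        decomposition: Decomposition,
        theta: Mapping[str, float] | None = None,
    ):
        self.network = network
        self.dec = decomposition
        self.theta = dict(theta or {})
        self.enc = _eng.compile_network(network, self.theta)
        names = network.names
        self.comp_index = {n: i for i, n in enumerate(names)}
        self.leader_idx = np.array(
            [self.comp_index[n] for n in decomposition.leaders], dtype=np.int64
        )
        zeta = network.zeta
        leaders = set(decomposition.leaders)
        sub_of = {n: i for i, sub in enumerate(decomposition.subsystems) for n in sub}
        self.sub_of = sub_of
        self._deps = [rxn.dependencies() & set(names) for rxn in network.reactions]
        self.leader_reactions: list[int] = []
        self.internal: list[list[int]] = [[] for _ in decomposition.subsystems]
        self.correction: list[list[int]] = [[] for _ in decomposition.subsystems]
        self._rxn_subsystem: dict[int, int | None] = {}
        for j in range(network.r):
            zl = zeta[j, self.leader_idx]
            touched = {sub_of[n] for n in self._deps[j] if n in sub_of}
            touched |= {
                sub_of[names[i]]
                for i in np.nonzero(zeta[j])[0]
                if names[i] in sub_of
            }
            if len(touched) > 1:
                raise ModelError("decomposition violates C1; run check_conditions")
            self._rxn_subsystem[j] = next(iter(touched)) if touched else None
            if np.any(zl != 0):
                self.leader_reactions.append(j)
                for n in self._deps[j]:
                    if n in sub_of:
                        self.correction[sub_of[n]].append(j)
            else:
                changed = [names[i] for i in np.nonzero(zeta[j])[0]]
                if changed:
                    self.internal[sub_of[changed[0]]].append(j)
        for i in range(len(self.correction)):
            self.correction[i] = sorted(set(self.correction[i]))

        # per-subsystem truncations; components the subsystem's internal
        # reactions never move (static pseudo-species such as parameters)
        # are ordered first so the filtered generator is block-diagonal over
        # contiguous blocks, enabling fast per-block propagation
        self.spaces: list[TruncatedStateSpace] = []
        self.sub_idx: list[np.ndarray] = []
        self._sub_states: list[np.ndarray] = []
        self._block_shape: list[tuple[int, int]] = []  # (n_blocks, block_size)
        for i, sub in enumerate(decomposition.subsystems):
            static = [
                n
                for n in sub
                if all(zeta[j, self.comp_index[n]] == 0 for j in self.internal[i])
            ]
            dynamic = [n for n in sub if n not in static]
            order = tuple(static + dynamic)
            space = TruncatedStateSpace(
                names=order,
                component_values=tuple(
                    tuple(network.species_by_name(n).values) for n in order
                ),
            )
            self.spaces.append(space)
            self.sub_idx.append(np.array([self.comp_index[n] for n in order], dtype=np.int64))
            self._sub_states.append(space.all_states())
            bs = 1
            for n in dynamic:
                bs *= network.species_by_name(n).truncation_size
            self._block_shape.append((space.size // bs, bs))

        # leader net-change -> matching reactions; by C2 the matching set
        # touches at most one subsystem, precomputed for the jump fast path
        self._delta_groups: dict[tuple, list[int]] = {}
        for j in self.leader_reactions:
            key = tuple(int(v) for v in zeta[j, self.leader_idx])
            self._delta_groups.setdefault(key, []).append(j)
        lead_pos = {n: k for k, n in enumerate(decomposition.leaders)}
        self._lead_pos = lead_pos
        self._delta_sub: dict[tuple, int | None] = {}
        self._delta_dep_pos: dict[tuple, tuple[int, ...]] = {}
        for key, js in self._delta_groups.items():
            subs = {self._rxn_subsystem[j] for j in js} - {None}
            if len(subs) > 1:
                raise ModelError("decomposition violates C2; run check_conditions")
            self._delta_sub[key] = next(iter(subs)) if subs else None
            dep: set[str] = set()
            for j in js:
                dep |= self._deps[j] & leaders
            self._delta_dep_pos[key] = tuple(sorted(lead_pos[n] for n in dep))

        # leader positions whose values enter subsystem i's generator
        self._gen_dep_pos: list[tuple[int, ...]] = []
        for i in range(len(decomposition.subsystems)):
            dep = set()
            for j in self.internal[i] + self.correction[i]:
                dep |= self._deps[j] & leaders
            self._gen_dep_pos.append(tuple(sorted(lead_pos[n] for n in dep)))

        self._A_cache: dict = {}
        self._B_cache: dict = {}
        self._rate_cache: dict = {}
        self._init_cache: dict = {}
        self._scratch = [
            tuple(np.empty(space.size) for _ in range(3)) for space in self.spaces
        ]

    # --- assembly helpers --------------------------------------------------

    def n_subsystems(self) -> int:
        return len(self.spaces)

    def full_leader_state(self, leader_state: Sequence[float]) -> np.ndarray:
        """Full component vector with leader values set, all else zero."""
        x = np.zeros(self.network.n)
        x[self.leader_idx] = np.asarray(leader_state, dtype=float)
        return x

    def assembled_states(self, i: int, leader_state: Sequence[float]) -> np.ndarray:
        """(S_i, n) full-state matrix over subsystem i's truncation."""
        S = self.spaces[i].size
        X = np.zeros((S, self.network.n))
        X[:, self.leader_idx] = np.asarray(leader_state, dtype=float)[None, :]
        X[:, self.sub_idx[i]] = self._sub_states[i]
        return X

    def _reaction_rates(self, j: int, leader_state: np.ndarray):
        """Propensity of reaction ``j`` at the given leader state.

        Returns ``(subsystem, vector)`` where vector runs over the touched
        subsystem's states, or ``(None, scalar)`` for leader-only reactions.
        """
        i = self._rxn_subsystem[j]
        dep_lead = sorted(
            self.comp_index[n] for n in self._deps[j] if n in set(self.dec.leaders)
        )
        full = np.asarray(leader_state, dtype=float)
        key = (j, tuple(full[list(self.dec.leaders).index(self.network.names[d])] for d in dep_lead)) if dep_lead else (j,)
        if key in self._rate_cache:
            return self._rate_cache[key]
        if i is None:
            x = self.full_leader_state(full)
            val = _eng.eval_propensities(self.enc, x[None, :])[0, j]
            out = (None, float(val))
        else:
            X = self.assembled_states(i, full)
            out = (i, _eng.eval_propensities(self.enc, X)[:, j].copy())
        self._rate_cache[key] = out
        return out

    def _generator(self, i: int, leader_state: np.ndarray):
        """Filtered generator of subsystem ``i`` at a fixed leader state:
        internal sub-CME plus the no-jump correction on the diagonal.
        Returns ``(data, indices, indptr, alpha)``."""
        key = (i, tuple(leader_state[p] for p in self._gen_dep_pos[i]))
        hit = self._A_cache.get(key)
        if hit is not None:
            return hit
        space = self.spaces[i]
        S = space.size
        X = self.assembled_states(i, leader_state)
        lam = _eng.eval_propensities(self.enc, X)
        strides = space._strides()
        sub_states = self._sub_states[i]
        zeta = self.network.zeta
        rows, cols, data = [], [], []
        diag = np.zeros(S)
        src = np.arange(S, dtype=np.int64)
        for j in self.internal[i]:
            lj = lam[:, j]
            active = lj > 0
            if not np.any(active):
                continue
            target = np.zeros(S, dtype=np.int64)
            valid = active.copy()
            zsub = zeta[j, self.sub_idx[i]]
            for c in range(len(self.sub_idx[i])):
                if zsub[c] == 0:
                    target += space.positions(c, sub_states[:, c]) * strides[c]
                else:
                    pos = space.positions(c, sub_states[:, c] + zsub[c])
                    valid &= pos >= 0
                    target += np.where(pos >= 0, pos, 0) * strides[c]
            inside = valid & active
            rows.append(target[inside])
            cols.append(src[inside])
            data.append(lj[inside])
            diag[active] -= lj[active]  # outflow incl. truncation loss
        for j in self.correction[i]:
            diag -= lam[:, j]
        rows.append(src)
        cols.append(src)
        data.append(diag)
        A = sp.csr_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(S, S),
        )
        alpha = float(np.max(-A.diagonal())) if S else 0.0
        out = self._build_propagator(i, A, alpha)
        self._A_cache[key] = out
        return out

    _EIG_BLOCK_CAP = 64

    def _build_propagator(self, i: int, A: sp.csr_matrix, alpha: float):
        """Choose the propagation route for a filtered generator.

        When the subsystem's static components split the generator into
        many small contiguous diagonal blocks, each block is diagonalized
        once (deduplicated across blocks) so a propagation step costs two
        small dense matvecs instead of a Poisson-series sweep; validated
        against uniformization at build time, with fallback on any
        numerical doubt."""
        nb, bs = self._block_shape[i]
        unif = ("unif", A.data, A.indices, A.indptr, alpha)
        if nb < 2 or bs > self._EIG_BLOCK_CAP:
            return unif
        dense = A.toarray()
        # confirm block-diagonality (guards against unexpected couplings)
        for b in range(nb):
            sl = slice(b * bs, (b + 1) * bs)
            if np.abs(dense[sl, :]).sum() > np.abs(dense[sl, sl]).sum():
                return unif
        uniq: dict[bytes, int] = {}
        bmap = np.empty(nb, dtype=np.int64)
        mats = []
        for b in range(nb):
            block = dense[b * bs : (b + 1) * bs, b * bs : (b + 1) * bs]
            key = block.tobytes()
            if key not in uniq:
                uniq[key] = len(mats)
                mats.append(block)
            bmap[b] = uniq[key]
        nu = len(mats)
        V = np.empty((nu, bs, bs))
        Vinv = np.empty((nu, bs, bs))
        lam = np.empty((nu, bs))
        for u, block in enumerate(mats):
            w_eig, v_eig = np.linalg.eig(block)
            if np.abs(w_eig.imag).max(initial=0.0) > 1e-9 * (1 + np.abs(w_eig.real).max()):
                return unif
            try:
                vinv = np.linalg.inv(v_eig)
            except np.linalg.LinAlgError:
                return unif
            V[u] = v_eig.real
            Vinv[u] = vinv.real
            lam[u] = w_eig.real
        prop = ("eig", V, Vinv, lam, bmap, bs)
        # cross-check against uniformization on a generic vector
        v0 = np.full(A.shape[0], 1.0 / A.shape[0])
        tau = 1.0 / max(alpha, 1.0)
        ref = _eng._expmv_unif(A.data, A.indices, A.indptr, v0, tau, alpha, 1e-13)
        trial = v0.copy()
        _eng._eig_block_propagate(V, Vinv, lam, bmap, trial, tau, bs)
        if np.abs(trial - ref).max() > 1e-9:
            return unif
        return prop

    def _jump_matrix(self, i: int, delta_key: tuple, leader_state: np.ndarray):
        """Bayes-update matrix for subsystem ``i`` at a leader jump with net
        change ``delta_key`` from pre-jump leader state; ``None`` when no
        matching reaction involves the subsystem (filter unchanged)."""
        js = self._delta_groups.get(delta_key)
        if js is None:
            raise ModelError(f"leader net change {delta_key} matches no reaction")
        if self._delta_sub.get(delta_key) != i:
            return None
        key = (
            i,
            delta_key,
            tuple(leader_state[p] for p in self._delta_dep_pos[delta_key]),
        )
        hit = self._B_cache.get(key)
        if hit is not None:
            return hit
        space = self.spaces[i]
        S = space.size
        X = self.assembled_states(i, leader_state)
        lam = _eng.eval_propensities(self.enc, X)
        strides = space._strides()
        sub_states = self._sub_states[i]
        zeta = self.network.zeta
        B = sp.csr_matrix((S, S))
        for j in js:
            lj = lam[:, j]
            zsub = zeta[j, self.sub_idx[i]]
            if np.all(zsub == 0):
                B = B + sp.diags(lj)
                continue
            target = np.zeros(S, dtype=np.int64)
            valid = lj > 0
            for c in range(len(self.sub_idx[i])):
                if zsub[c] == 0:
                    target += space.positions(c, sub_states[:, c]) * strides[c]
                else:
                    pos = space.positions(c, sub_states[:, c] + zsub[c])
                    valid &= pos >= 0
                    target += np.where(pos >= 0, pos, 0) * strides[c]
            src = np.arange(S, dtype=np.int64)
            B = B + sp.csr_matrix(
                (lj[valid], (target[valid], src[valid])), shape=(S, S)
            )
        B = B.tocsr()
        out = (B.data, B.indices, B.indptr)
        self._B_cache[key] = out
        return out

    # --- filter operations -------------------------------------------------

    def initial_filters(
        self, init: InitialDistribution | None = None
    ) -> list[FollowerFilter]:
        """Per-subsystem filters from a product-form initial law (follower
        components independent of the leader at time zero)."""
        init = init if init is not None else self.network.initial
        if init is None or init.marginals is None:
            raise ModelError("filtered FSP requires a product-form initial distribution")
        base = self._init_cache.get(id(init))
        if base is None:
            base = []
            for i, space in enumerate(self.spaces):
                vec = np.ones(1)
                for c, name in enumerate(space.names):
                    vec = np.kron(
                        vec,
                        init.marginal_for(name).pmf_on(np.asarray(space.component_values[c])),
                    )
                base.append(FollowerFilter(subsystem=i, probs=vec / vec.sum(), t=0.0))
            self._init_cache[id(init)] = base
        return [f.copy() for f in base]

    def propagate(
        self, filt: FollowerFilter, leader_state: Sequence[float], dt: float
    ) -> FollowerFilter:
        """Advance one filter over an interval with the leader held fixed."""
        if dt < 0:
            raise ValueError("negative propagation interval")
        if dt == 0:
            return filt
        prop = self._generator(filt.subsystem, np.asarray(leader_state, dtype=float))
        if prop[0] == "eig":
            _tag, V, Vinv, lam, bmap, bs = prop
            s = _eng._eig_block_propagate(V, Vinv, lam, bmap, filt.probs, float(dt), bs)
        else:
            _tag, data, indices, indptr, alpha = prop
            term, new, out = self._scratch[filt.subsystem]
            s = _eng._expmv_unif_inplace(
                data, indices, indptr, filt.probs, float(dt), alpha, 1e-12, term, new, out
            )
        if s < _MASS_FLOOR:
            raise FilterMassLost("follower filter mass annihilated during propagation")
        filt.probs /= s
        filt.t += dt
        filt.log_norm += np.log(s)
        return filt

    def jump_update(
        self,
        filt: FollowerFilter,
        pre_jump_leader_state: Sequence[float],
        leader_net_change: Sequence[float],
    ) -> FollowerFilter:
        """Bayes update of one filter at an observed leader jump."""
        delta_key = tuple(int(v) for v in leader_net_change)
        B = self._jump_matrix(
            filt.subsystem, delta_key, np.asarray(pre_jump_leader_state, dtype=float)
        )
        if B is None:
            return filt
        w = _eng._csr_matvec(*B, filt.probs)
        s = float(w.sum())
        if s < _MASS_FLOOR:
            raise FilterJumpImpossible(
                f"leader jump {delta_key} impossible under subsystem {filt.subsystem} filter"
            )
        filt.probs = w / s
        filt.log_norm += np.log(s)
        return filt

    def advance(
        self,
        filters: list[FollowerFilter],
        leader_traj: LeaderTrajectory,
        query_times: Sequence[float],
    ) -> list[list[FollowerFilter]]:
        """Run all filters along a leader path; snapshot at query times.

        At a time that is both a jump and a query, the post-jump filter is
        reported (right-continuity).
        """
        query_times = np.asarray(query_times, dtype=float)
        if query_times.size and (
            query_times.min() < leader_traj.t0 - 1e-12
            or query_times.max() > leader_traj.t_end + 1e-12
        ):
            raise ValueError("query times outside the leader trajectory span")
        snapshots: list[list[FollowerFilter]] = []
        qpos = 0
        nq = query_times.size
        t = leader_traj.t0
        n_jumps = leader_traj.n_jumps
        times = leader_traj.times
        deltas = leader_traj.deltas
        propagate = self.propagate
        nf = len(filters)
        # lazy propagation: segments sharing a filter's generator key are
        # merged into a single matrix-exponential action, flushed only when
        # the generator changes, a jump touches the filter, or a snapshot
        # is due
        pending = [0.0] * nf
        pend_key: list = [None] * nf
        pend_state: list = [None] * nf

        def flush(i: int) -> None:
            if pending[i] > 0.0:
                propagate(filters[i], pend_state[i], pending[i])
                pending[i] = 0.0

        def accumulate(x_seg, dt) -> None:
            for i in range(nf):
                key = tuple(x_seg[p] for p in self._gen_dep_pos[i])
                if pending[i] > 0.0 and key != pend_key[i]:
                    flush(i)
                pending[i] += dt
                pend_key[i] = key
                pend_state[i] = x_seg

        for k in range(n_jumps + 1):
            last = k == n_jumps
            seg_end = leader_traj.t_end if last else times[k]
            x_seg = leader_traj.final_state() if last else leader_traj.state_before(k)
            while qpos < nq and query_times[qpos] < seg_end:
                dt = query_times[qpos] - t
                if dt > 0:
                    accumulate(x_seg, dt)
                for i in range(nf):
                    flush(i)
                t = query_times[qpos]
                snapshots.append([f.copy() for f in filters])
                qpos += 1
            dt = seg_end - t
            if dt > 0:
                accumulate(x_seg, dt)
            t = seg_end
            if not last:
                delta_key = (
                    (int(deltas[k][0]),)
                    if deltas.shape[1] == 1
                    else tuple(int(v) for v in deltas[k])
                )
                i_rel = self._delta_sub[delta_key]  # <=1 subsystem touched (C2)
                if i_rel is not None:
                    flush(i_rel)
                    self.jump_update(filters[i_rel], x_seg, deltas[k])
                while qpos < nq and abs(query_times[qpos] - t) <= 1e-12:
                    for i in range(nf):
                        flush(i)
                    snapshots.append([f.copy() for f in filters])
                    qpos += 1
        for i in range(nf):
            flush(i)
        while qpos < nq:
            snapshots.append([f.copy() for f in filters])
            qpos += 1
        return snapshots


# ---------------------------------------------------------------------------
# operation-level wrappers
# ---------------------------------------------------------------------------


def filtered_propagate(
    filt: FollowerFilter,
    network: ReactionNetwork,
    decomposition: Decomposition,
    leader_state: Sequence[float],
    dt: float,
    theta: Mapping[str, float] | None = None,
    engine: FilteredFspEngine | None = None,
) -> FollowerFilter:
    eng = engine or FilteredFspEngine(network, decomposition, theta)
    return eng.propagate(filt, leader_state, dt)


def filtered_jump_update(
    filt: FollowerFilter,
    network: ReactionNetwork,
    decomposition: Decomposition,
    pre_jump_leader_state: Sequence[float],
    leader_net_change: Sequence[float],
    theta: Mapping[str, float] | None = None,
    engine: FilteredFspEngine | None = None,
) -> FollowerFilter:
    eng = engine or FilteredFspEngine(network, decomposition, theta)
    return eng.jump_update(filt, pre_jump_leader_state, leader_net_change)


def filter_along_trajectory(
    network: ReactionNetwork,
    decomposition: Decomposition,
    leader_traj: LeaderTrajectory,
    query_times: Sequence[float],
    init: InitialDistribution | None = None,
    theta: Mapping[str, float] | None = None,
    engine: FilteredFspEngine | None = None,
    filters: list[FollowerFilter] | None = None,
) -> list[list[FollowerFilter]]:
    """Solve all subsystem conditionals along a leader path; returns one
    list of per-subsystem filter snapshots per query time."""
    eng = engine or FilteredFspEngine(network, decomposition, theta)
    if filters is None:
        filters = eng.initial_filters(init)
    return eng.advance(filters, leader_traj, query_times)
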