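"""The Rao-Blackwellized CME solver: Monte Carlo over leader trajectories
combined with exact follower conditionals from the filtered FSP.

The joint law factorizes as an expectation over leader paths of
``1(X_lead(t)=x) * prod_i pi_{Z_i|X}(t, z_i)``; sampling N leader paths by
whole-system SSA (discarding followers) and averaging the indicator times
the product of follower filters gives the RB estimate.  With every species
leader-side this reduces to the plain Monte Carlo empirical distribution;
with every species follower-side it reduces to the FSP.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .decompose import Decomposition
from .filtered_cme import (
    FilteredFspEngine,
    FilterJumpImpossible,
    FilterMassLost,
    FollowerFilter,
    LeaderTrajectory,
    extract_leader_path,
)
from .model import InitialDistribution, ModelError, ReactionNetwork
from .simulate import ssa_ensemble, state_key

__all__ = [
    "RbEstimate",
    "MarginalTable",
    "rb_cme_solve",
    "marginalize",
    "dense_joint",
    "l1_error",
    "sample_leader_path_thinning",
]


class RbSolverError(RuntimeError):
    pass


@dataclass
class RbEstimate:
    """N-particle RB estimate at a single time: leader states plus the
    per-subsystem follower filters, with (uniform) weights."""

    network: ReactionNetwork
    decomposition: Decomposition
    t: float
    leader_states: np.ndarray  # (M, n_leaders)
    filters: list[list[FollowerFilter]]
    weights: np.ndarray
    N: int
    engine: FilteredFspEngine | None = None

    @property
    def n_particles(self) -> int:
        return int(self.leader_states.shape[0])


@dataclass
class MarginalTable:
    """Dense probability table over named components, with any probability
    of leader states outside the declared truncation reported separately."""

    names: tuple[str, ...]
    values: tuple[tuple[float, ...], ...]
    table: np.ndarray
    outside: float = 0.0


def rb_cme_solve(
    network: ReactionNetwork,
    decomposition: Decomposition,
    init: InitialDistribution | None,
    t: float,
    N: int,
    seed: int,
    theta: Mapping[str, float] | None = None,
    engine: FilteredFspEngine | None = None,
    leader_sampler: str = "ssa",
) -> RbEstimate:
    """Solve the CME at time ``t`` with N Rao-Blackwellized particles.

    Leader paths are drawn by whole-system SSA with follower discard
    (``leader_sampler="ssa"``) or, as a cross-validation alternative, by
    conditional-intensity thinning (``"thinning"``).  Particles whose
    filters fail (an impossible leader jump under a truncated filter) are
    dropped; more than half failing is an error.
    """
    init = init if init is not None else network.initial
    if init is None:
        raise ModelError("an initial distribution is required")
    eng = engine or FilteredFspEngine(network, decomposition, theta)
    leader_states: list[np.ndarray] = []
    filters: list[list[FollowerFilter]] = []
    failures = 0
    if leader_sampler == "ssa":
        trajectories = ssa_ensemble(network, theta, init, 0.0, t, N, seed)
        for traj in trajectories:
            path = extract_leader_path(traj, network, decomposition)
            try:
                fs = eng.initial_filters(init)
                snaps = eng.advance(fs, path, [t])
                leader_states.append(path.final_state())
                filters.append(snaps[0])
            except (FilterJumpImpossible, FilterMassLost):
                failures += 1
    elif leader_sampler == "thinning":
        for k, child in enumerate(np.random.SeedSequence(seed).spawn(N)):
            try:
                path, fs = sample_leader_path_thinning(
                    network, decomposition, t, child, init=init, theta=theta, engine=eng
                )
                leader_states.append(path.final_state())
                filters.append(fs)
            except (FilterJumpImpossible, FilterMassLost):
                failures += 1
    else:
        raise ValueError(f"unknown leader sampler {leader_sampler!r}")
    if failures > N / 2:
        raise RbSolverError(f"follower filters failed on {failures}/{N} particles")
    M = len(leader_states)
    n_lead = len(decomposition.leaders)
    return RbEstimate(
        network=network,
        decomposition=decomposition,
        t=float(t),
        leader_states=(
            np.asarray(leader_states, dtype=float).reshape(M, n_lead)
        ),
        filters=filters,
        weights=np.full(M, 1.0 / M) if M else np.empty(0),
        N=N,
        engine=eng,
    )


# ---------------------------------------------------------------------------
# marginals and dense assembly
# ---------------------------------------------------------------------------


def _component_values(network: ReactionNetwork, name: str) -> tuple[float, ...]:
    return tuple(network.species_by_name(name).values)


def marginalize(estimate: RbEstimate, components: Sequence[str]) -> MarginalTable:
    """Probability table over the requested components.

    Leader marginals are weighted empirical counts of the kept trajectories;
    follower marginals are weighted averages of the filters; joints across
    blocks use the conditional-independence product per particle (so a joint
    over two subsystems is ``E[q^i (x) q^j]``, not the product of marginals).
    """
    network, dec = estimate.network, estimate.decomposition
    components = tuple(components)
    sub_of = {n: i for i, sub in enumerate(dec.subsystems) for n in sub}
    lead_pos = {n: i for i, n in enumerate(dec.leaders)}
    blocks: dict[object, list[str]] = {}
    for name in components:
        if name in lead_pos:
            blocks.setdefault("lead", []).append(name)
        elif name in sub_of:
            blocks.setdefault(sub_of[name], []).append(name)
        else:
            raise ModelError(f"unknown component {name!r}")
    values = tuple(_component_values(network, n) for n in components)
    shape = tuple(len(v) for v in values)
    out = np.zeros(shape)
    outside = 0.0

    # per-block machinery
    lead_names = blocks.get("lead", [])
    lead_cols = np.array([lead_pos[n] for n in lead_names], dtype=np.int64)
    lead_vals = [np.asarray(_component_values(network, n)) for n in lead_names]
    sub_blocks = [(i, blocks[i]) for i in blocks if i != "lead"]
    sub_reshapes = {}
    for i, names_i in sub_blocks:
        space = (estimate.engine.spaces[i] if estimate.engine is not None else None)
        if space is None:
            raise RbSolverError("estimate lacks its engine; cannot marginalize followers")
        keep_axes = tuple(space.names.index(n) for n in names_i)
        sub_reshapes[i] = (space.sizes, keep_axes)

    for w, lead, fs in zip(estimate.weights, estimate.leader_states, estimate.filters):
        factors = []
        if lead_names:
            pos = []
            ok = True
            for c, valsc in zip(lead_cols, lead_vals):
                hits = np.nonzero(np.isclose(valsc, lead[c], atol=1e-9))[0]
                if hits.size == 0:
                    ok = False
                    break
                pos.append(int(hits[0]))
            if not ok:
                outside += w
                continue
            onehot = np.zeros([len(v) for v in lead_vals])
            onehot[tuple(pos)] = 1.0
            factors.append((lead_names, onehot))
        for i, names_i in sub_blocks:
            sizes, keep_axes = sub_reshapes[i]
            q = fs[i].probs.reshape(sizes)
            drop = tuple(a for a in range(len(sizes)) if a not in keep_axes)
            qm = q.sum(axis=drop) if drop else q
            qm = np.transpose(qm, np.argsort(np.argsort(keep_axes)))
            factors.append((names_i, qm))
        # outer product of block factors, then align axes to request order
        block_names = [n for names_b, _ in factors for n in names_b]
        joint = np.ones(())
        for _, f in factors:
            joint = np.multiply.outer(joint, f)
        perm = [block_names.index(n) for n in components]
        out += w * np.transpose(joint, perm)
    return MarginalTable(names=components, values=values, table=out, outside=outside)


def dense_joint(estimate: RbEstimate) -> MarginalTable:
    """Full joint table on the product truncation, in network component
    order.  Particles are grouped by leader state so the follower outer
    products are formed once per particle."""
    network, dec = estimate.network, estimate.decomposition
    names = network.names
    values = tuple(_component_values(network, n) for n in names)
    shape = tuple(len(v) for v in values)
    # follower axes follow the engine's (possibly reordered) subsystem spaces
    block_order = list(dec.leaders) + [
        n for i in range(len(dec.subsystems)) for n in estimate.engine.spaces[i].names
    ]
    perm = [block_order.index(n) for n in names]
    lead_vals = [np.asarray(_component_values(network, n)) for n in dec.leaders]
    lead_shape = tuple(len(v) for v in lead_vals)
    sub_shapes = [
        tuple(estimate.engine.spaces[i].sizes) for i in range(len(dec.subsystems))
    ]
    work = np.zeros(lead_shape + tuple(s for ss in sub_shapes for s in ss))
    outside = 0.0
    groups: dict[tuple, list[int]] = {}
    for k, lead in enumerate(estimate.leader_states):
        groups.setdefault(state_key(lead), []).append(k)
    for lead_key, idxs in groups.items():
        pos = []
        ok = True
        for c, valsc in enumerate(lead_vals):
            hits = np.nonzero(np.isclose(valsc, lead_key[c], atol=1e-9))[0]
            if hits.size == 0:
                ok = False
                break
            pos.append(int(hits[0]))
        if not ok:
            outside += float(estimate.weights[idxs].sum())
            continue
        acc = np.zeros(tuple(s for ss in sub_shapes for s in ss))
        for k in idxs:
            prod = np.ones(())
            for i in range(len(dec.subsystems)):
                prod = np.multiply.outer(prod, estimate.filters[k][i].probs.reshape(sub_shapes[i]))
            acc += estimate.weights[k] * prod
        work[tuple(pos)] += acc
    # axes of `work` are in block order; permute to network order
    full = np.transpose(work, perm)
    return MarginalTable(names=names, values=values, table=full.reshape(shape), outside=outside)


def l1_error(estimate_table, reference_table, outside_est: float = 0.0, outside_ref: float = 0.0) -> float:
    """L1 distance between two probability tables (arrays of matching shape
    or sparse dict tables); mass outside a shared truncation enters as a
    separate coordinate.  The result lies in [0, 2]."""
    if isinstance(estimate_table, Mapping) or isinstance(reference_table, Mapping):
        a = dict(estimate_table) if isinstance(estimate_table, Mapping) else None
        b = dict(reference_table) if isinstance(reference_table, Mapping) else None
        if a is None or b is None:
            raise ValueError("mixed dense/sparse tables: densify first")
        keys = set(a) | set(b)
        return float(sum(abs(a.get(k, 0.0) - b.get(k, 0.0)) for k in keys))
    a = np.asarray(estimate_table, dtype=float)
    b = np.asarray(reference_table, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"mismatched table shapes {a.shape} vs {b.shape}")
    return float(np.abs(a - b).sum() + abs(outside_est - outside_ref))


def dense_from_empirical(
    table: Mapping[tuple, float], values: Sequence[Sequence[float]]
) -> tuple[np.ndarray, float]:
    """Densify a sparse empirical table onto a product truncation; mass at
    states outside the truncation is returned separately."""
    vals = [np.asarray(v, dtype=float) for v in values]
    out = np.zeros(tuple(len(v) for v in vals))
    outside = 0.0
    for key, p in table.items():
        pos = []
        ok = True
        for c, v in enumerate(key):
            hits = np.nonzero(np.isclose(vals[c], float(v), atol=1e-9))[0]
            if hits.size == 0:
                ok = False
                break
            pos.append(int(hits[0]))
        if ok:
            out[tuple(pos)] += p
        else:
            outside += p
    return out, outside


# ---------------------------------------------------------------------------
# conditional-intensity (thinning) leader sampler — cross-validation oracle
# ---------------------------------------------------------------------------


def sample_leader_path_thinning(
    network: ReactionNetwork,
    decomposition: Decomposition,
    t_end: float,
    seed,
    init: InitialDistribution | None = None,
    theta: Mapping[str, float] | None = None,
    engine: FilteredFspEngine | None = None,
) -> tuple[LeaderTrajectory, list[FollowerFilter]]:
    """Sample a leader path from its exact marginal law without simulating
    follower states, by Ogata thinning of the conditional intensity
    ``E_pi[lambda_j(x_lead, Z)]``; the follower filters ride along and are
    returned at ``t_end``.  Statistically equivalent to whole-system SSA
    with follower discard; retained as an independent cross-check."""
    eng = engine or FilteredFspEngine(network, decomposition, theta)
    init = init if init is not None else network.initial
    rng = np.random.default_rng(seed)
    filters = eng.initial_filters(init)
    leader = np.array(
        [init.marginal_for(n).sample(rng) for n in decomposition.leaders], dtype=float
    )
    x0 = leader.copy()
    t = 0.0
    times, states, deltas = [], [], []
    while True:
        rates = []
        lbar = 0.0
        for j in eng.leader_reactions:
            i, v = eng._reaction_rates(j, leader)
            rates.append((j, i, v))
            lbar += float(np.max(v)) if i is not None else float(v)
        if lbar <= 0.0:
            for f in filters:
                eng.propagate(f, leader, t_end - t)
            break
        tau = rng.exponential(1.0 / lbar)
        if t + tau >= t_end:
            for f in filters:
                eng.propagate(f, leader, t_end - t)
            break
        for f in filters:
            eng.propagate(f, leader, tau)
        t += tau
        e = np.array(
            [
                float(v) if i is None else float(filters[i].probs @ v)
                for _j, i, v in rates
            ]
        )
        etot = float(e.sum())
        if rng.random() * lbar < etot:
            # aggregate by leader net change, then Bayes-update the filters
            zeta = network.zeta
            keys = [
                tuple(int(z) for z in zeta[j, eng.leader_idx]) for j, _i, _v in rates
            ]
            uniq: dict[tuple, float] = {}
            for key, ej in zip(keys, e):
                uniq[key] = uniq.get(key, 0.0) + ej
            ks = list(uniq.keys())
            probs = np.array([uniq[k] for k in ks]) / etot
            delta = np.array(ks[rng.choice(len(ks), p=probs)], dtype=float)
            for f in filters:
                eng.jump_update(f, leader, delta)
            leader = leader + delta
            times.append(t)
            states.append(leader.copy())
            deltas.append(delta.copy())
    m = len(times)
    nl = len(decomposition.leaders)
    path = LeaderTrajectory(
        t0=0.0,
        t_end=float(t_end),
        names=decomposition.leaders,
        x0=x0,
        times=np.asarray(times),
        states=np.asarray(states, dtype=float).reshape(m, nl),
        deltas=np.asarray(deltas, dtype=float).reshape(m, nl),
    )
    return path, filters
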