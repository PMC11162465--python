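"""Filtered-CME correctness: rejection-sampling and full-joint oracles for
the reconstructed prediction/correction/jump operators."""

import numpy as np
import pytest

import rbcme
from rbcme import fixtures as fx
from rbcme.decompose import Decomposition
from rbcme.filtered_cme import (
    FilteredFspEngine,
    FollowerFilter,
    LeaderTrajectory,
    extract_leader_path,
)
from rbcme.model import (
    InitialDistribution,
    LinearCombination,
    Marginal,
    MassAction,
    Reaction,
    Species,
    build_network,
)


@pytest.fixture(scope="module")
def gene_birth_toy():
    """A two-state gene switching on/off while driving a leader birth
    process at rate 2*G."""
    net = build_network(
        [Species("G", state_list=(0, 1)), Species("X", truncation_size=30)],
        [
            Reaction({}, {"G": 1}, LinearCombination(terms=(((0.8,), None), ((-0.8,), "G")))),
            Reaction({"G": 1}, {}, MassAction(1.2)),
            Reaction({"G": 1}, {"G": 1, "X": 1}, MassAction(2.0)),
        ],
        init=InitialDistribution(
            marginals={
                "G": Marginal("categorical", values=(0, 1), probs=(0.5, 0.5)),
                "X": Marginal("point", value=0),
            }
        ),
    )
    dec = Decomposition(leaders=("X",), subsystems=(("G",),), sizes=(2,))
    return net, dec


def test_propagate_matches_rejection_sampling_oracle(gene_birth_toy):
    """The no-leader-jump conditional from filtered propagation must match
    the conditional estimated by rejection from SSA runs sharing the
    leader's no-jump event."""
    net, dec = gene_birth_toy
    eng = FilteredFspEngine(net, dec)
    dt = 0.7
    filt = eng.initial_filters()[0]
    eng.propagate(filt, np.array([0.0]), dt)
    trajs = rbcme.ssa_ensemble(net, None, net.initial, 0.0, dt, 200_000, 42)
    kept = np.array([tr.state_at(dt)[0] for tr in trajs if tr.state_at(dt)[1] == 0])
    p_hat = kept.mean()
    se = kept.std() / np.sqrt(len(kept))
    assert filt.probs[1] == pytest.approx(p_hat, abs=4 * se)


def test_jump_update_matches_conditional_of_jumping_runs(gene_birth_toy):
    """Bayes at an observed leader birth: weights proportional to the
    birth propensity 2*G, so the posterior concentrates on G=1."""
    net, dec = gene_birth_toy
    eng = FilteredFspEngine(net, dec)
    filt = eng.initial_filters()[0]
    eng.propagate(filt, np.array([0.0]), 0.3)
    pre = filt.probs.copy()
    eng.jump_update(filt, np.array([0.0]), np.array([1.0]))
    # hand Bayes: weights (0, 2) elementwise
    expect = pre * np.array([0.0, 2.0])
    np.testing.assert_allclose(filt.probs, expect / expect.sum(), atol=1e-12)


def test_jump_update_hand_bayes_weights_proportional_to_state():
    """Leader birth at rate k*z on a two-point follower {0, 2} with equal
    mass: the posterior is {0, 1}."""
    net = build_network(
        [Species("Z", state_list=(0, 2)), Species("X", truncation_size=10)],
        [Reaction({}, {"X": 1}, LinearCombination(terms=(((1.0,), "Z"),)))],
        init=InitialDistribution(
            marginals={
                "Z": Marginal("categorical", values=(0, 2), probs=(0.5, 0.5)),
                "X": Marginal("point", value=0),
            }
        ),
    )
    dec = Decomposition(leaders=("X",), subsystems=(("Z",),), sizes=(2,))
    eng = FilteredFspEngine(net, dec)
    filt = eng.initial_filters()[0]
    eng.jump_update(filt, np.array([0.0]), np.array([1.0]))
    np.testing.assert_allclose(filt.probs, [0.0, 1.0], atol=1e-15)


def test_jump_with_constant_propensity_leaves_filter_unchanged(chain6):
    """A leader jump whose matching reactions have z-independent
    propensities and no follower stoichiometry is uninformative."""
    dec = rbcme.optimal_decomposition(chain6, max_subsystem_size=100)
    eng = FilteredFspEngine(chain6, dec)
    filt = eng.initial_filters()[1]  # subsystem (S4, S5)
    before = filt.probs.copy()
    # degradation of S6 has constant-in-followers propensity: Delta = -1 on S6
    eng.jump_update(filt, np.array([2.0, 3.0]), np.array([0.0, -1.0]))
    np.testing.assert_array_equal(filt.probs, before)


def test_follower_shift_when_jump_moves_follower(chain6):
    """The conversion S3 -> S4 moves follower S4: the filter support shifts
    deterministically because the propensity (x3) is constant in the
    followers."""
    dec = rbcme.optimal_decomposition(chain6, max_subsystem_size=100)
    eng = FilteredFspEngine(chain6, dec)
    space = eng.spaces[1]
    filt = FollowerFilter(subsystem=1, probs=np.zeros(space.size), t=0.0)
    filt.probs[space.index_of([2, 5])] = 1.0
    eng.jump_update(filt, np.array([3.0, 1.0]), np.array([-1.0, 0.0]))
    # Delta(-1 on S3) aggregates conversion (shift S4 by +1, rate x3) and
    # degradation of S3 (no shift, rate 0.6 x3): posterior splits 1 : 0.6
    expect = np.zeros(space.size)
    expect[space.index_of([3, 5])] = 1.0 / 1.6
    expect[space.index_of([2, 5])] = 0.6 / 1.6
    np.testing.assert_allclose(filt.probs, expect, atol=1e-12)


def test_no_leader_coupling_reduces_to_fsp(chain2):
    """With every species follower-side the filtered equation is the CME:
    propagation equals (renormalized) fsp_solve."""
    dec = Decomposition(leaders=(), subsystems=(("S1", "S2"),), sizes=(100,))
    eng = FilteredFspEngine(chain2, dec)
    filt = eng.initial_filters()[0]
    path = LeaderTrajectory(
        t0=0.0, t_end=10.0, names=(), x0=np.empty(0),
        times=np.empty(0), states=np.empty((0, 0)), deltas=np.empty((0, 0)),
    )
    snaps = eng.advance([filt], path, [10.0])
    space = rbcme.truncated_space(chain2)
    sol = rbcme.fsp_solve(chain2, space, chain2.initial, 10.0)
    assert rbcme.l1_error(snaps[0][0].probs, sol.p / sol.p.sum()) < 1e-7


def test_propagation_agrees_with_adaptive_ode_route(gene_birth_toy):
    """The uniformization kernel and a stiff ODE solve of the same filtered
    generator agree to tight tolerance."""
    import scipy.sparse as sp
    from scipy.integrate import solve_ivp

    net, dec = gene_birth_toy
    eng = FilteredFspEngine(net, dec)
    _tag, data, indices, indptr, _alpha = eng._generator(0, np.array([0.0]))
    A = sp.csr_matrix((data, indices, indptr), shape=(2, 2))
    p0 = np.array([0.5, 0.5])
    res = solve_ivp(lambda t, y: A @ y, (0, 0.7), p0, rtol=1e-10, atol=1e-14)
    ode = res.y[:, -1] / res.y[:, -1].sum()
    filt = FollowerFilter(subsystem=0, probs=p0.copy(), t=0.0)
    eng.propagate(filt, np.array([0.0]), 0.7)
    np.testing.assert_allclose(filt.probs, ode, atol=1e-8)


def test_single_state_subsystem_stays_point_mass():
    net = build_network(
        [Species("Z", state_list=(1,)), Species("X", truncation_size=10)],
        [Reaction({}, {"X": 1}, LinearCombination(terms=(((1.5,), "Z"),)))],
        init=InitialDistribution.point({"Z": 1, "X": 0}),
    )
    dec = Decomposition(leaders=("X",), subsystems=(("Z",),), sizes=(1,))
    traj = rbcme.ssa_simulate(net, None, [1, 0], 0.0, 5.0, 3)
    path = extract_leader_path(traj, net, dec)
    snaps = rbcme.filter_along_trajectory(net, dec, path, [1.0, 5.0])
    for snap in snaps:
        np.testing.assert_array_equal(snap[0].probs, [1.0])


def test_factorized_filters_match_unpartitioned_joint_filter():
    """Per-subsystem filters versus the same filtered equations run on the
    joint follower space (single subsystem): the factorization implied by
    C1/C2 must be exact (miniature toggle, <= 1e-6)."""
    net = fx.make_toggle(protein_truncation=40)
    traj = rbcme.ssa_simulate(net, None, [1, 0, 0, 0], 0.0, 60.0, 19)
    dec = Decomposition(leaders=("G1", "G2"), subsystems=(("P1",), ("P2",)), sizes=(40, 40))
    joint_dec = Decomposition(
        leaders=("G1", "G2"), subsystems=(("P1", "P2"),), sizes=(1600,)
    )
    path = extract_leader_path(traj, net, dec)
    qs = rbcme.filter_along_trajectory(net, dec, path, [20.0, 60.0])
    joint = rbcme.filter_along_trajectory(net, joint_dec, path, [20.0, 60.0])
    for snap_f, snap_j in zip(qs, joint):
        prod = np.outer(snap_f[0].probs, snap_f[1].probs).ravel()
        assert rbcme.l1_error(prod, snap_j[0].probs) < 1e-6


def test_zero_normalizer_jump_is_signaled():
    from rbcme.filtered_cme import FilterJumpImpossible

    net = build_network(
        [Species("Z", state_list=(0, 1)), Species("X", truncation_size=10)],
        [Reaction({}, {"X": 1}, LinearCombination(terms=(((3.0,), "Z"),)))],
        init=InitialDistribution.point({"Z": 0, "X": 0}),
    )
    dec = Decomposition(leaders=("X",), subsystems=(("Z",),), sizes=(2,))
    eng = FilteredFspEngine(net, dec)
    filt = FollowerFilter(subsystem=0, probs=np.array([1.0, 0.0]), t=0.0)
    with pytest.raises(FilterJumpImpossible):
        eng.jump_update(filt, np.array([0.0]), np.array([1.0]))
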