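"""RB-CME solver: limiting cases, marginalization semantics, L1 metric,
and statistical exactness of the two leader-path samplers."""

import numpy as np
import pytest
from scipy import stats

import rbcme
from rbcme import fixtures as fx
from rbcme.decompose import Decomposition
from rbcme.rb_solver import dense_from_empirical


def test_all_leader_matches_empirical_with_shared_seeds(chain2):
    dec = Decomposition(leaders=("S1", "S2"), subsystems=(), sizes=())
    est = rbcme.rb_cme_solve(chain2, dec, None, 10.0, 300, seed=7)
    trajs = rbcme.ssa_ensemble(chain2, None, chain2.initial, 0.0, 10.0, 300, 7)
    emp = rbcme.empirical_distribution(trajs, 10.0)
    space = rbcme.truncated_space(chain2)
    de, out = dense_from_empirical(emp, space.component_values)
    dj = rbcme.dense_joint(est)
    assert rbcme.l1_error(dj.table, de, dj.outside, out) == 0.0


def test_all_follower_equals_fsp_for_any_n(chain2):
    dec = Decomposition(leaders=(), subsystems=(("S1", "S2"),), sizes=(100,))
    space = rbcme.truncated_space(chain2)
    sol = rbcme.fsp_solve(chain2, space, chain2.initial, 10.0)
    pn = (sol.p / sol.p.sum()).reshape(space.sizes)
    for N in (1, 5):
        est = rbcme.rb_cme_solve(chain2, dec, None, 10.0, N, seed=3)
        dj = rbcme.dense_joint(est)
        assert rbcme.l1_error(dj.table, pn) < 1e-6


def test_rb_estimate_reproduces_fsp_joint_within_mc_error(chain3):
    """Rao-Blackwell exactness: averaging leader indicators times follower
    filters over sampled paths converges to the full FSP joint."""
    net = fx.linear_chain(3, truncation=8)
    space = rbcme.truncated_space(net)
    sol = rbcme.fsp_solve(net, space, net.initial, 4.0)
    pn = (sol.p / sol.p.sum()).reshape(space.sizes)
    dec = rbcme.optimal_decomposition(net, max_subsystem_size=100)
    est = rbcme.rb_cme_solve(net, dec, None, 4.0, 4000, seed=11)
    dj = rbcme.dense_joint(est)
    err = rbcme.l1_error(dj.table, pn, dj.outside, 0.0)
    # leader-marginal MC noise dominates: prefactor ~ sum sqrt(p_S3) < 3
    assert err < 3.5 / np.sqrt(4000)


def test_marginal_tables_normalize_and_match_leader_empirical(chain6):
    dec = rbcme.optimal_decomposition(chain6, max_subsystem_size=100)
    est = rbcme.rb_cme_solve(chain6, dec, None, 5.0, 400, seed=2)
    for comp in ("S3", "S1", ("S1", "S4")):
        comp = (comp,) if isinstance(comp, str) else comp
        m = rbcme.marginalize(est, comp)
        assert m.table.sum() + m.outside == pytest.approx(1.0, abs=1e-9)
    # leader marginal equals the empirical distribution of kept paths
    m = rbcme.marginalize(est, ("S3",))
    vals, counts = np.unique(est.leader_states[:, 0], return_counts=True)
    for v, c in zip(vals, counts):
        idx = int(v)
        if idx < len(m.table):
            assert m.table[idx] == pytest.approx(c / est.n_particles, abs=1e-12)


def test_cross_subsystem_joint_uses_conditional_independence_product():
    """Joint over two subsystems must be E[q1 (x) q2], not the product of
    marginals: checked against the full FSP on a correlated chain."""
    net = fx.linear_chain(6, truncation=5)
    space = rbcme.truncated_space(net)
    sol = rbcme.fsp_solve(net, space, net.initial, 3.0, method="uniformization")
    pj = (sol.p / sol.p.sum()).reshape(space.sizes)
    ref = pj.sum(axis=(0, 2, 3, 5))  # joint of (S2, S5)
    dec = rbcme.optimal_decomposition(net, max_subsystem_size=100)
    est = rbcme.rb_cme_solve(net, dec, None, 3.0, 3000, seed=21)
    m = rbcme.marginalize(est, ("S2", "S5"))
    err_joint = rbcme.l1_error(m.table, ref)
    # product-of-marginals is measurably worse than the mixture joint
    ma = rbcme.marginalize(est, ("S2",)).table
    mb = rbcme.marginalize(est, ("S5",)).table
    err_prod = rbcme.l1_error(np.outer(ma, mb), ref)
    assert err_joint < 0.08
    assert err_joint <= err_prod + 0.02


def test_leader_marginal_error_comparable_to_plain_mc(chain6_reference):
    """Both methods estimate the leader system by the same empirical
    protocol, so at equal N their leader-marginal errors are comparable
    (the Rao-Blackwell gain lives in the followers)."""
    ref = chain6_reference
    net = fx.linear_chain(6)
    dec = rbcme.optimal_decomposition(net, max_subsystem_size=100)
    lead_ref = ref["table"].sum(axis=(0, 1, 3, 4))  # joint of (S3, S6)
    rb_errs, mc_errs = [], []
    for rep in range(3):
        est = rbcme.rb_cme_solve(net, dec, None, 10.0, 2000, seed=600 + rep)
        m = rbcme.marginalize(est, ("S3", "S6"))
        rb_errs.append(rbcme.l1_error(m.table, lead_ref) + m.outside)
        trajs = rbcme.ssa_ensemble(net, None, net.initial, 0, 10.0, 2000, 700 + rep)
        emp = rbcme.empirical_distribution(trajs, 10.0)
        lead_emp: dict = {}
        for key, p in emp.items():
            lk = (key[2], key[5])
            lead_emp[lk] = lead_emp.get(lk, 0.0) + p
        de, out = dense_from_empirical(
            lead_emp, (ref["space"].component_values[2], ref["space"].component_values[5])
        )
        mc_errs.append(rbcme.l1_error(de, lead_ref, out, 0.0))
    ratio = np.mean(rb_errs) / np.mean(mc_errs)
    assert 0.5 < ratio < 2.0


def test_l1_error_examples():
    assert rbcme.l1_error(np.array([0.2, 0.8]), np.array([0.2, 0.8])) == 0.0
    assert rbcme.l1_error({(0,): 1.0}, {(5,): 1.0}) == 2.0
    with pytest.raises(ValueError):
        rbcme.l1_error(np.zeros(3), np.zeros(4))


def test_thinning_and_ssa_leader_samplers_statistically_indistinguishable(chain3):
    """The conditional-intensity thinning sampler and whole-system SSA with
    follower discard must induce the same RB estimates (two-sample test on
    per-replicate L1 errors)."""
    net = fx.linear_chain(3, truncation=8)
    space = rbcme.truncated_space(net)
    sol = rbcme.fsp_solve(net, space, net.initial, 3.0)
    pn = (sol.p / sol.p.sum()).reshape(space.sizes)
    dec = rbcme.optimal_decomposition(net, max_subsystem_size=100)

    def errors(sampler, seeds):
        out = []
        for s in seeds:
            est = rbcme.rb_cme_solve(
                net, dec, None, 3.0, 250, seed=s, leader_sampler=sampler
            )
            dj = rbcme.dense_joint(est)
            out.append(rbcme.l1_error(dj.table, pn, dj.outside, 0.0))
        return out

    e_ssa = errors("ssa", range(100, 112))
    e_thin = errors("thinning", range(300, 312))
    assert stats.mannwhitneyu(e_ssa, e_thin).pvalue > 0.01
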