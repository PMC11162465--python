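"""Filtering: likelihoods, the exact FSP filter, bootstrap PF, and RB-PF."""

import numpy as np
import pytest

import rbcme
from rbcme import fixtures as fx
from rbcme.filtering import Channel, ObservationModel, systematic_resample
from rbcme.model import (
    InitialDistribution,
    MassAction,
    Reaction,
    Species,
    build_network,
)
from rbcme.simulate import ObservationSeries

from conftest import joint_error_vs_exact


def birth_toy(trunc=50):
    return build_network(
        [Species("X", trunc)],
        [
            Reaction({}, {"X": 1}, MassAction(2.0)),
            Reaction({"X": 1}, {}, MassAction(0.5)),
        ],
        init=InitialDistribution.point({"X": 0}),
    )


def identity_obs(sigma=1.0, species="X"):
    return ObservationModel(channels=(Channel("identity", species=species),), sigma=(sigma,))


def test_gaussian_likelihood_values():
    om = identity_obs(sigma=1.0)
    names = ("X",)
    peak = rbcme.gaussian_likelihood(om, [3.0], [3.0], names)
    off = rbcme.gaussian_likelihood(om, [4.0], [3.0], names)
    assert off / peak == pytest.approx(np.exp(-0.5))
    assert peak == pytest.approx(1 / np.sqrt(2 * np.pi))


def test_thresholded_readout_cannot_distinguish_subthreshold_counts():
    om = ObservationModel(
        channels=(Channel("threshold", species="mRNA", threshold=7),), sigma=(1.0,)
    )
    names = ("mRNA",)
    for y in (-0.3, 0.0, 1.2):
        assert rbcme.gaussian_likelihood(om, [y], [5.0], names) == pytest.approx(
            rbcme.gaussian_likelihood(om, [y], [3.0], names)
        )


def test_exact_filter_without_information_reduces_to_fsp():
    net = birth_toy()
    space = rbcme.truncated_space(net)
    # near-flat likelihood: huge sigma
    om = identity_obs(sigma=1e8)
    series = ObservationSeries(times=np.array([2.0, 4.0]), values=np.zeros((2, 1)), model=om)
    post = rbcme.exact_fsp_filter(net, space, series)
    for k, t in enumerate(series.times):
        sol = rbcme.fsp_solve(net, space, net.initial, t)
        assert rbcme.l1_error(post.snapshots[k], sol.p / sol.p.sum()) < 1e-5


def test_bootstrap_pf_flat_likelihood_matches_empirical():
    net = birth_toy()
    om = identity_obs(sigma=1e8)
    series = ObservationSeries(times=np.array([3.0]), values=np.zeros((1, 1)), model=om)
    post = rbcme.bootstrap_pf(net, series, 400, 9)
    states, weights = post.snapshots[0]
    np.testing.assert_allclose(weights, 1 / 400)


def test_bootstrap_pf_converges_to_exact_filter():
    """Root-N convergence of the PF posterior to the exact filter on a
    one-species birth-death toy."""
    net = birth_toy()
    space = rbcme.truncated_space(net)
    truth = rbcme.ssa_simulate(net, None, [0], 0.0, 6.0, 33)
    om = identity_obs(sigma=1.0)
    series = rbcme.generate_observations(truth, om, [2.0, 4.0, 6.0], 7)
    exact = rbcme.exact_fsp_filter(net, space, series)
    errs = []
    for N in (200, 3200):
        reps = []
        for rep in range(3):
            pf = rbcme.bootstrap_pf(net, series, N, 100 + rep)
            reps.append(joint_error_vs_exact(pf, exact, 2))
        errs.append(np.mean(reps))
    assert errs[1] < errs[0] / 2.0  # expect ~4x at 16x the particles


def test_rbpf_beats_pf_at_tenth_the_samples(toggle_filter_setup):
    """Fig. 6C pattern: per-time joint L1 of the RB-PF at N versus the
    bootstrap PF at 10N, both against the exact FSP filter."""
    s = toggle_filter_setup
    rbpf = rbcme.rb_particle_filter(
        s["network"], s["decomposition"], s["series"], 500, 5
    )
    pf = rbcme.bootstrap_pf(s["network"], s["series"], 5000, 5)
    for k in range(len(s["series"].times)):
        e_rb = joint_error_vs_exact(rbpf, s["exact"], k)
        e_pf = joint_error_vs_exact(pf, s["exact"], k)
        assert e_rb < e_pf, f"time {k}: rbpf {e_rb} vs pf {e_pf}"


def test_rbpf_posteriors_normalized_and_likelihood_finite(toggle_filter_setup):
    s = toggle_filter_setup
    post = rbcme.rb_particle_filter(
        s["network"], s["decomposition"], s["series"], 100, 3
    )
    assert np.isfinite(post.log_marginal_likelihood)
    for k in range(len(post.times)):
        est = post.snapshots[k]
        assert est.weights.sum() == pytest.approx(1.0, abs=1e-9)
        for fs in est.filters:
            for f in fs:
                assert f.probs.sum() == pytest.approx(1.0, abs=1e-9)


def test_rbpf_robust_across_observation_noise_levels(toggle_sigma_sweep):
    """Fig. 6F pattern: the average error does not blow up monotonically as
    sigma varies over {0.5, 1, 2, 4}."""
    avg_errs = list(toggle_sigma_sweep.values())
    assert max(avg_errs) < 3 * min(avg_errs)


def test_rbpf_with_flat_likelihood_matches_rb_cme_solver(chain6):
    """With no informative observations the RB-PF marginals coincide with
    the RB-CME solver's (the no-observation equivalence)."""
    om = ObservationModel(channels=(Channel("identity", species="S3"),), sigma=(1e9,))
    series = ObservationSeries(times=np.array([5.0]), values=np.zeros((1, 1)), model=om)
    dec = rbcme.optimal_decomposition(chain6, max_subsystem_size=100, obs_model=om)
    post = rbcme.rb_particle_filter(chain6, dec, series, 300, 17)
    est_pf = post.snapshots[0]
    est_rb = rbcme.rb_cme_solve(chain6, dec, None, 5.0, 300, seed=23)
    for comp in ("S1", "S3", "S5"):
        a = rbcme.marginalize(est_pf, (comp,)).table
        b = rbcme.marginalize(est_rb, (comp,)).table
        assert rbcme.l1_error(a, b) < 0.25  # two independent 300-particle runs
    # uniform weights, no resampling triggered under a flat likelihood
    np.testing.assert_allclose(est_pf.weights, 1 / 300, atol=1e-12)


def test_systematic_resample_preserves_weight_proportions():
    rng = np.random.default_rng(0)
    w = np.array([0.5, 0.25, 0.25])
    idx = systematic_resample(np.repeat(w / 100, 100).reshape(3, 100).T.ravel(), rng)
    assert idx.shape == (300,)
    counts = np.bincount(systematic_resample(w, rng), minlength=3)
    assert counts.sum() == 3
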