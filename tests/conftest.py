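import numpy as np
import pytest

import rbcme
from rbcme import fixtures as fx


@pytest.fixture(scope="session")
def chain2():
    return fx.linear_chain(2)


@pytest.fixture(scope="session")
def chain3():
    return fx.linear_chain(3)


@pytest.fixture(scope="session")
def chain6():
    return fx.linear_chain(6)


@pytest.fixture(scope="session")
def chain6_reference():
    """Analytic product-Poisson reference for the 6-chain at t=10."""
    net = fx.linear_chain(6)
    space = rbcme.truncated_space(net)
    means = fx.linear_chain_analytic_means(6, 10.0)
    table, outside = fx.poisson_product_dense(means, space.component_values)
    return {"space": space, "means": means, "table": table, "outside": outside}


@pytest.fixture(scope="session")
def toggle():
    return fx.make_toggle()


@pytest.fixture(scope="session")
def toggle_filter_setup():
    """One simulated toggle trajectory with 10 noisy readouts of P1, the
    reduced-space exact FSP filter, and the auto decomposition — shared by
    the filtering tests."""
    net = fx.make_toggle()
    obs_model = fx.toggle_observation_model(sigma=1.0)
    traj = rbcme.ssa_simulate(net, None, [1, 0, 0, 0], 0.0, 200.0, 7)
    times = np.arange(20.0, 201.0, 20.0)
    series = rbcme.generate_observations(traj, obs_model, times, 11)
    space = rbcme.truncated_space(net, overrides={"P1": range(50), "P2": range(50)})
    exact = rbcme.exact_fsp_filter(net, space, series)
    dec = rbcme.optimal_decomposition(net, max_subsystem_size=200, obs_model=obs_model)
    return {
        "network": net,
        "obs_model": obs_model,
        "series": series,
        "space": space,
        "exact": exact,
        "decomposition": dec,
    }


@pytest.fixture(scope="session")
def toggle_sigma_sweep(toggle_filter_setup):
    """Average RB-PF error vs the exact filter across observation noise
    levels sigma in {0.5, 1, 2, 4} on one toggle trajectory (Fig. 6F-style
    sweep); expensive, computed once."""
    s = toggle_filter_setup
    net = s["network"]
    traj = rbcme.ssa_simulate(net, None, [1, 0, 0, 0], 0.0, 200.0, 7)
    times = np.arange(20.0, 201.0, 20.0)
    out = {}
    for sigma in (0.5, 1.0, 2.0, 4.0):
        om = fx.toggle_observation_model(sigma=sigma)
        series = rbcme.generate_observations(traj, om, times, 11)
        exact = rbcme.exact_fsp_filter(net, s["space"], series)
        rbpf = rbcme.rb_particle_filter(net, s["decomposition"], series, 200, 5)
        out[sigma] = float(
            np.mean(
                [joint_error_vs_exact(rbpf, exact, k) for k in range(len(times))]
            )
        )
    return out


@pytest.fixture(scope="session")
def yeast():
    return fx.yeast_model("insilico")


def joint_error_vs_exact(post, exact, k):
    """L1 distance of a PF/RB-PF posterior to the exact filter, restricting
    the comparison to the exact filter's (smaller) truncation and counting
    mass outside it as error."""
    pe, _ = exact.dense(k)
    d, out = post.dense(k)
    sl = tuple(slice(0, s) for s in pe.shape)
    dd = d[sl]
    return float(np.abs(dd - pe).sum() + (d.sum() - dd.sum()) + out)
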