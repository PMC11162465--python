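"""Intrinsic/extrinsic noise decomposition: time averages, the two
estimation routes, and their concordance on synthetic populations."""

import numpy as np
import pytest

import rbcme
from rbcme import fixtures as fx
from rbcme.noise import (
    CellPopulationData,
    decompose_from_models,
    decompose_from_trajectories,
    trajectory_time_averages,
)
from rbcme.model import (
    InitialDistribution,
    MassAction,
    ParameterSpec,
    Reaction,
    Species,
    build_network,
)
from rbcme.simulate import ObservationSeries, Trajectory


def birth_death_net(grid=(2.0, 6.0), prior=(0.5, 0.5)):
    return build_network(
        [Species("X", 60)],
        [
            Reaction({}, {"X": 1}, MassAction("k")),
            Reaction({"X": 1}, {}, MassAction(1.0)),
        ],
        params=[ParameterSpec("k", grid, prior)],
        init=InitialDistribution.point({"X": 0}),
    )


def staircase(levels, dt, t_end):
    times = np.arange(dt, t_end + dt / 2, dt)
    states = np.array([[levels[min(int(t // dt), len(levels) - 1)]] for t in times])
    return Trajectory(
        t0=0.0, t_end=t_end, x0=np.array([levels[0]]),
        times=times[:-1], states=states[:-1], seed=0,
    )


def test_time_averages_constant_and_two_level():
    const = Trajectory(
        t0=0.0, t_end=10.0, x0=np.array([3.0]),
        times=np.empty(0), states=np.empty((0, 1)), seed=0,
    )
    m, m2, v = trajectory_time_averages(const, 10.0)
    assert (m, v) == (3.0, 0.0)
    two = Trajectory(
        t0=0.0, t_end=10.0, x0=np.array([0.0]),
        times=np.array([5.0]), states=np.array([[10.0]]), seed=0,
    )
    m, m2, v = trajectory_time_averages(two, 10.0)
    assert m == pytest.approx(5.0) and v == pytest.approx(25.0)


def test_time_average_of_birth_death_matches_poisson_stationary():
    net = birth_death_net()
    traj = rbcme.ssa_simulate(net, {"k": 4.0}, [0], 0.0, 5000.0, 13)
    m, _, v = trajectory_time_averages(traj, 5000.0)
    assert m == pytest.approx(4.0, abs=0.3)
    assert v == pytest.approx(4.0, abs=0.6)


def test_identical_deterministic_cells_have_zero_extrinsic():
    cells = [staircase([0, 10], 5.0, 10.0) for _ in range(5)]
    pop = CellPopulationData(cells=cells, horizon=10.0)
    res = decompose_from_trajectories(pop)
    assert res.extrinsic == pytest.approx(0.0, abs=1e-12)
    assert res.intrinsic == pytest.approx(25.0)


def test_constant_heterogeneous_cells_have_zero_intrinsic():
    levels = [2.0, 4.0, 6.0, 8.0]
    cells = [
        Trajectory(
            t0=0.0, t_end=10.0, x0=np.array([lv]),
            times=np.empty(0), states=np.empty((0, 1)), seed=0,
        )
        for lv in levels
    ]
    pop = CellPopulationData(cells=cells, horizon=10.0)
    res = decompose_from_trajectories(pop, min_nonzero=1)
    assert res.intrinsic == 0.0
    assert res.extrinsic == pytest.approx(np.var(levels))
    assert 0.0 <= res.extrinsic_fraction <= 1.0


def test_single_cell_extrinsic_undefined():
    pop = CellPopulationData(cells=[staircase([1, 2], 5.0, 10.0)], horizon=10.0)
    with pytest.raises(ValueError):
        decompose_from_trajectories(pop)


def test_two_point_mixture_recovers_closed_form():
    """Cells drawn from a birth-death mixture k in {2, 6}: intrinsic is
    E[k/gamma] and extrinsic Var(k/gamma) (Poisson-mixture oracle)."""
    net = birth_death_net()
    rng_truths = []
    cells = []
    for seed, child in enumerate(np.random.SeedSequence(77).spawn(40)):
        rng = np.random.default_rng(child)
        k = float(rng.choice([2.0, 6.0]))
        rng_truths.append(k)
        cells.append(
            rbcme.ssa_simulate(net, {"k": k}, [0], 0.0, 1500.0, int(rng.integers(2**31)))
        )
    pop = CellPopulationData(cells=cells, horizon=1500.0)
    res = decompose_from_trajectories(pop)
    ks = np.array(rng_truths)
    assert res.intrinsic == pytest.approx(np.mean(ks), rel=0.15)
    assert res.extrinsic == pytest.approx(np.var(ks), rel=0.35)


def test_model_route_identity_holds_to_machine_precision():
    net = birth_death_net()
    models = [(net, {"k": 2.0}), (net, {"k": 6.0}), (net, {"k": 6.0})]
    res = decompose_from_models(models, species="X")
    assert res.total == res.intrinsic + res.extrinsic  # exact identity
    assert res.intrinsic == pytest.approx(np.mean([2, 6, 6]), rel=1e-4)
    assert res.extrinsic == pytest.approx(np.var([2.0, 6.0, 6.0]), rel=1e-4)


def test_shared_model_population_has_zero_extrinsic():
    net = birth_death_net()
    res = decompose_from_models([(net, {"k": 4.0})] * 3, species="X")
    assert res.extrinsic == pytest.approx(0.0, abs=1e-12)


def test_route_equivalence_on_synthetic_population():
    """Trajectory-route and model-route decompositions agree on a synthetic
    population whose per-cell models are known exactly."""
    net = birth_death_net()
    truths = []
    cells = []
    for child in np.random.SeedSequence(123).spawn(60):
        rng = np.random.default_rng(child)
        k = float(rng.choice([2.0, 6.0]))
        truths.append(k)
        cells.append(
            rbcme.ssa_simulate(net, {"k": k}, [0], 0.0, 2000.0, int(rng.integers(2**31)))
        )
    pop = CellPopulationData(cells=cells, horizon=2000.0)
    res_t = decompose_from_trajectories(pop)
    res_m = decompose_from_models([(net, {"k": k}) for k in truths], species="X")
    assert res_t.intrinsic == pytest.approx(res_m.intrinsic, rel=0.12)
    assert res_t.extrinsic == pytest.approx(res_m.extrinsic, rel=0.30)
    assert res_t.total == pytest.approx(res_m.total, rel=0.12)


def test_inactive_cells_are_excluded():
    active = [staircase([0, 10], 5.0, 10.0) for _ in range(3)]
    dead = Trajectory(
        t0=0.0, t_end=10.0, x0=np.array([0.0]),
        times=np.empty(0), states=np.empty((0, 1)), seed=0,
    )
    pop = CellPopulationData(cells=active + [dead], horizon=10.0)
    res = decompose_from_trajectories(pop)
    assert res.n_cells == 3 and res.n_excluded == 1
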