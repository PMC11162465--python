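"""Benchmark networks with analytic oracles, and a synthetic cell-population
generator.

Four fixtures ship with the package:

* an expandable linear chain (production / conversion / degradation, all
  mass-action) whose CME is solved exactly by a product-Poisson law with
  ODE-evolving means — the reference for all convergence tests;
* a repressilator (three Hill-repressed gene-expression units);
* a genetic toggle switch (two mutually repressing expression units) —
  repressilator and toggle rate constants are representative defaults
  chosen to produce the qualitative regimes (oscillation; bistable
  switching), not published values;
* a three-gene-state yeast transcription model (inactive state G0, active
  states G1/G2 transcribing at rates kp1 and kp1+kp2, mRNA degradation
  rate constant 1) with discrete parameter grids for the in-silico and
  experimental regimes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.stats import poisson

from .filtering import Channel, ObservationModel
from .model import (
    Hill,
    InitialDistribution,
    LinearCombination,
    MassAction,
    ParameterSpec,
    Reaction,
    ReactionNetwork,
    Species,
    build_network,
)
from .noise import CellPopulationData
from .simulate import generate_observations, ssa_simulate

__all__ = [
    "linear_chain",
    "linear_chain_analytic_means",
    "linear_chain_analytic_solution",
    "poisson_product_dense",
    "poisson_sqrt_prefactor_sum",
    "make_repressilator",
    "make_toggle",
    "toggle_observation_model",
    "yeast_model",
    "yeast_observation_model",
    "grid_prior_sampler",
    "generate_cell_population",
]


# ---------------------------------------------------------------------------
# linear chain
# ---------------------------------------------------------------------------

CHAIN_K_PRODUCTION_FIRST = 2.4  # k_1
CHAIN_K_DEGRADATION = 0.6  # k_{3i-1}, i < n
CHAIN_K_CONVERSION = 1.0  # k_{3i}
CHAIN_K_PRODUCTION_INTERNAL = 0.9  # k_{3i+1}
CHAIN_K_DEGRADATION_LAST = 1.6  # k_{3n-1}
CHAIN_INIT_MEAN = 0.5


def linear_chain(n: int, truncation: int = 10) -> ReactionNetwork:
    """Linear conversion chain S_1 -> S_2 -> ... -> S_n with production and
    degradation; ``3n - 1`` mass-action reactions in total.

    Reaction-index mapping: k_1 produces S_1; for each i < n, k_{3i-1}
    degrades S_i, k_{3i} converts S_i into S_{i+1}, and k_{3i+1} produces
    S_{i+1}; k_{3n-1} degrades S_n.  Every species starts with an
    independent Poisson(0.5) count.
    """
    if n < 2:
        raise ValueError("the chain needs at least two species")
    species = [Species(f"S{i+1}", truncation_size=truncation) for i in range(n)]
    reactions = [Reaction({}, {"S1": 1}, MassAction(CHAIN_K_PRODUCTION_FIRST))]
    for i in range(1, n):
        reactions.append(
            Reaction({f"S{i}": 1}, {}, MassAction(CHAIN_K_DEGRADATION))
        )
        reactions.append(
            Reaction({f"S{i}": 1}, {f"S{i+1}": 1}, MassAction(CHAIN_K_CONVERSION))
        )
        reactions.append(Reaction({}, {f"S{i+1}": 1}, MassAction(CHAIN_K_PRODUCTION_INTERNAL)))
    reactions.append(Reaction({f"S{n}": 1}, {}, MassAction(CHAIN_K_DEGRADATION_LAST)))
    init = InitialDistribution.product_poisson(
        {sp.name: CHAIN_INIT_MEAN for sp in species}
    )
    return build_network(species, reactions, init=init)


def _chain_mean_system(n: int) -> tuple[np.ndarray, np.ndarray]:
    """dm/dt = K m + b for the chain's Poisson means."""
    K = np.zeros((n, n))
    b = np.zeros(n)
    b[0] = CHAIN_K_PRODUCTION_FIRST
    for i in range(n - 1):
        K[i, i] -= CHAIN_K_DEGRADATION + CHAIN_K_CONVERSION
        K[i + 1, i] += CHAIN_K_CONVERSION
        b[i + 1] = CHAIN_K_PRODUCTION_INTERNAL
    K[n - 1, n - 1] -= CHAIN_K_DEGRADATION_LAST
    return K, b


def linear_chain_analytic_means(n: int, t: float) -> np.ndarray:
    """Exact Poisson means at time ``t`` via the augmented matrix
    exponential of the affine mean ODE."""
    K, b = _chain_mean_system(n)
    M = np.zeros((n + 1, n + 1))
    M[:n, :n] = K
    M[:n, n] = b
    y0 = np.concatenate([np.full(n, CHAIN_INIT_MEAN), [1.0]])
    return (expm(M * t) @ y0)[:n]


def linear_chain_analytic_solution(n: int, t: float) -> dict:
    """Product-Poisson law of the chain at ``t``: per-species means and
    callables for joint probabilities."""
    means = linear_chain_analytic_means(n, t)
    return {
        "means": means,
        "pmf": lambda x: float(np.prod(poisson.pmf(np.asarray(x), means))),
    }


def poisson_product_dense(
    means: Sequence[float], values: Sequence[Sequence[float]]
) -> tuple[np.ndarray, float]:
    """Dense product-Poisson table on a truncation plus the tail mass
    outside it."""
    vec = np.ones(1)
    for m, vals in zip(means, values):
        vec = np.kron(vec, poisson.pmf(np.asarray(vals), m))
    table = vec.reshape([len(v) for v in values])
    return table, float(1.0 - table.sum())


def poisson_sqrt_prefactor_sum(means: Sequence[float]) -> float:
    """``sum_x sqrt(p(x))`` for an independent-Poisson law (factorizes into
    a product of per-species sums over the full lattice)."""
    out = 1.0
    for m in means:
        kmax = int(m + 40 * np.sqrt(m + 1.0)) + 20
        out *= float(np.sqrt(poisson.pmf(np.arange(kmax), m)).sum())
    return out


# ---------------------------------------------------------------------------
# repressilator
# ---------------------------------------------------------------------------


def make_repressilator(
    vmax: float = 10.0,
    K: float = 40.0,
    n_hill: float = 3.0,
    k_translate: float = 2.0,
    deg_mrna: float = 1.0,
    deg_protein: float = 0.2,
    mrna_truncation: int = 20,
    protein_truncation: int = 200,
) -> ReactionNetwork:
    """Three gene-expression units whose proteins cyclically repress the
    next unit's transcription (Hill repression).  Default rates give
    sustained stochastic oscillation with mRNA below 20 and protein below
    200 copies."""
    species = []
    reactions = []
    for i in range(3):
        species.append(Species(f"M{i+1}", truncation_size=mrna_truncation))
    for i in range(3):
        species.append(Species(f"P{i+1}", truncation_size=protein_truncation))
    for i in range(3):
        repressor = f"P{(i - 1) % 3 + 1}"
        reactions.append(
            Reaction(
                {},
                {f"M{i+1}": 1},
                Hill(vmax=vmax, K=K, n=n_hill, regulator=repressor, mode="repressor"),
            )
        )
        reactions.append(Reaction({f"M{i+1}": 1}, {}, MassAction(deg_mrna)))
        reactions.append(
            Reaction({f"M{i+1}": 1}, {f"M{i+1}": 1, f"P{i+1}": 1}, MassAction(k_translate))
        )
        reactions.append(Reaction({f"P{i+1}": 1}, {}, MassAction(deg_protein)))
    init = InitialDistribution.point(
        {"M1": 2, "M2": 0, "M3": 0, "P1": 20, "P2": 0, "P3": 0}
    )
    return build_network(species, reactions, init=init)


# ---------------------------------------------------------------------------
# genetic toggle switch
# ---------------------------------------------------------------------------


def make_toggle(
    k_produce: float = 5.0,
    k_deg: float = 0.25,
    k_on: float = 0.1,
    k_repress: float = 0.02,
    protein_truncation: int = 200,
) -> ReactionNetwork:
    """Two gene-expression units repressing each other: each active gene
    produces its protein, and the opposing protein deactivates the gene by
    binding.  Default rates give bistable switching with protein dwell
    levels near ``k_produce / k_deg``."""
    species = [
        Species("G1", state_list=(0, 1)),
        Species("G2", state_list=(0, 1)),
        Species("P1", truncation_size=protein_truncation),
        Species("P2", truncation_size=protein_truncation),
    ]
    reactions = []
    for i, j in ((1, 2), (2, 1)):
        g, p, q = f"G{i}", f"P{i}", f"P{j}"
        # activation: propensity k_on * (1 - g)
        reactions.append(
            Reaction(
                {},
                {g: 1},
                LinearCombination(terms=(((k_on,), None), ((-k_on,), g))),
            )
        )
        # deactivation by the opposing protein: k_repress * g * P_j
        reactions.append(Reaction({g: 1, q: 1}, {q: 1}, MassAction(k_repress)))
        reactions.append(Reaction({g: 1}, {g: 1, p: 1}, MassAction(k_produce)))
        reactions.append(Reaction({p: 1}, {}, MassAction(k_deg)))
    init = InitialDistribution.point({"G1": 1, "G2": 0, "P1": 0, "P2": 0})
    return build_network(species, reactions, init=init)


def toggle_observation_model(sigma: float = 1.0) -> ObservationModel:
    """The first protein is fluorescent and read out directly."""
    return ObservationModel(
        channels=(Channel("identity", species="P1"),), sigma=(float(sigma),)
    )


# ---------------------------------------------------------------------------
# yeast transcription model
# ---------------------------------------------------------------------------


def yeast_model(regime: str = "insilico", mrna_truncation: int | None = None) -> ReactionNetwork:
    """Three-gene-state transcription model: G0 <-> G1 <-> G2 with switching
    rates k1..k4; transcription at rate ``kp1*G1 + (kp1+kp2)*G2``; mRNA
    degradation rate constant 1.  Exactly one gene-state indicator is 1 at
    all times (enforced by the switching stoichiometry).

    ``regime`` selects the parameter grids: ``"insilico"`` (k1..k4 on
    {0,0.05,...,1}, kp on {1,...,10}, mRNA truncated to {0..20}) or
    ``"experimental"`` (k4 on {0,0.1,...,2}, kp1 on {0,8,...,80}, kp2 on
    {20,30,...,120}, mRNA truncated to {0..150}).  In both regimes k3's
    prior puts half its mass at zero — the uncertainty over whether there
    are one or two active gene states; all other priors are uniform.
    """

    def uniform_spec(name, grid):
        g = tuple(float(v) for v in grid)
        return ParameterSpec(name, g, tuple([1.0 / len(g)] * len(g)))

    def k3_spec(name, grid):
        g = tuple(float(v) for v in grid)
        assert g[0] == 0.0
        rest = len(g) - 1
        return ParameterSpec(name, g, (0.5,) + tuple([0.5 / rest] * rest))

    k_grid = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 10))
    if regime == "insilico":
        kp_grid = tuple(float(v) for v in range(1, 11))
        params = (
            uniform_spec("k1", k_grid),
            uniform_spec("k2", k_grid),
            k3_spec("k3", k_grid),
            uniform_spec("k4", k_grid),
            uniform_spec("kp1", kp_grid),
            uniform_spec("kp2", kp_grid),
        )
        trunc = 21 if mrna_truncation is None else mrna_truncation
    elif regime == "experimental":
        params = (
            uniform_spec("k1", k_grid),
            uniform_spec("k2", k_grid),
            k3_spec("k3", k_grid),
            uniform_spec("k4", tuple(np.round(np.arange(0.0, 2.0001, 0.1), 10))),
            uniform_spec("kp1", tuple(float(v) for v in range(0, 81, 8))),
            uniform_spec("kp2", tuple(float(v) for v in range(20, 121, 10))),
        )
        trunc = 151 if mrna_truncation is None else mrna_truncation
    else:
        raise ValueError(f"unknown regime {regime!r}")

    species = [
        Species("G0", state_list=(0, 1)),
        Species("G1", state_list=(0, 1)),
        Species("G2", state_list=(0, 1)),
        Species("mRNA", truncation_size=trunc),
    ]
    reactions = [
        Reaction({"G0": 1}, {"G1": 1}, MassAction("k1")),
        Reaction({"G1": 1}, {"G0": 1}, MassAction("k2")),
        Reaction({"G1": 1}, {"G2": 1}, MassAction("k3")),
        Reaction({"G2": 1}, {"G1": 1}, MassAction("k4")),
        Reaction(
            {},
            {"mRNA": 1},
            LinearCombination(terms=((("kp1",), "G1"), (("kp1", "kp2"), "G2"))),
        ),
        Reaction({"mRNA": 1}, {}, MassAction(1.0)),
    ]
    init = InitialDistribution.point({"G0": 1, "G1": 0, "G2": 0, "mRNA": 0})
    return build_network(species, reactions, params, init)


def yeast_observation_model(sigma: float = 0.1, threshold: float | None = None) -> ObservationModel:
    """mRNA readout channel: direct (in-silico) or thresholded — the
    microscopy platform reads zero unless the count exceeds 7
    (experimental)."""
    if threshold is None:
        ch = Channel("identity", species="mRNA")
    else:
        ch = Channel("threshold", species="mRNA", threshold=float(threshold))
    return ObservationModel(channels=(ch,), sigma=(float(sigma),))


# ---------------------------------------------------------------------------
# synthetic cell populations
# ---------------------------------------------------------------------------


def grid_prior_sampler(network: ReactionNetwork) -> Callable:
    """Draw each parameter independently from its grid prior."""

    def sample(rng: np.random.Generator) -> dict[str, float]:
        out = {}
        for spec in network.parameters:
            i = rng.choice(len(spec.grid), p=np.asarray(spec.prior))
            out[spec.name] = float(spec.grid[i])
        return out

    return sample


def generate_cell_population(
    base_model: ReactionNetwork,
    parameter_sampler: Callable,
    n_cells: int,
    T: float,
    dt: float,
    obs_model: ObservationModel,
    seed: int,
    keep_trajectories: bool = False,
    species: str = "mRNA",
) -> CellPopulationData:
    """Simulate a heterogeneous population: per cell, draw parameters, run
    an SSA trajectory from the model's initial condition, and read it out
    through the observation model on a ``dt`` grid.  The generating
    parameters are retained for recovery tests."""
    times = np.round(np.arange(dt, T + dt / 2, dt), 10)
    cells, trajectories, truths = [], [], []
    for k, child in enumerate(np.random.SeedSequence(seed).spawn(n_cells)):
        rng = np.random.default_rng(child)
        theta = parameter_sampler(rng)
        x0 = base_model.initial.sample_state(base_model, rng)
        traj = ssa_simulate(
            base_model, theta, x0, 0.0, float(T), int(rng.integers(0, 2**31 - 1))
        )
        series = generate_observations(
            traj, obs_model, times, int(rng.integers(0, 2**31 - 1))
        )
        cells.append(series)
        if keep_trajectories:
            trajectories.append(traj)
        truths.append(theta)
    pop = CellPopulationData(cells=cells, horizon=float(T), species=species, truths=truths)
    pop.trajectories = trajectories if keep_trajectories else None
    return pop
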