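"""Reaction-network models: species, kinetics, parameter grids, and the
parameter-augmented network used for cell-specific identification.

A network is a continuous-time Markov chain on copy-number vectors.  Each of
the ``r`` reactions carries a stoichiometric net change ``zeta_j`` and a
propensity ``lambda_j(theta, x)`` giving its firing rate at state ``x``.
Unknown rate parameters may be declared on finite grids with prior
probability vectors; :func:`augment_with_parameters` turns them into static
pseudo-species so that parameter inference becomes a filtering problem on an
augmented chain.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence, Union

import numpy as np

__all__ = [
    "Species",
    "MassAction",
    "Hill",
    "LinearCombination",
    "Reaction",
    "ParameterSpec",
    "Marginal",
    "InitialDistribution",
    "ReactionNetwork",
    "build_network",
    "propensity_eval",
    "augment_with_parameters",
    "network_to_json",
    "network_from_json",
]

RateRef = Union[float, int, str]


class ModelError(ValueError):
    """Raised for ill-formed networks, states, or parameter values."""


# ---------------------------------------------------------------------------
# species and kinetics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Species:
    """A chemical species together with its truncated state space.

    The admissible values are ``0, 1, ..., truncation_size - 1`` unless an
    explicit ``state_list`` is given (used for binary gene-state species and
    for parameter pseudo-species whose "states" are grid values).
    """

    name: str
    truncation_size: int = 0
    state_list: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.state_list is not None:
            values = tuple(float(v) for v in self.state_list)
            if len(values) < 1:
                raise ModelError(f"species {self.name!r}: empty state list")
            if any(b <= a for a, b in zip(values, values[1:])):
                raise ModelError(f"species {self.name!r}: state list must be increasing")
            object.__setattr__(self, "state_list", values)
            object.__setattr__(self, "truncation_size", len(values))
        elif self.truncation_size < 1:
            raise ModelError(f"species {self.name!r}: truncation_size must be >= 1")

    @property
    def values(self) -> np.ndarray:
        """Admissible values as a float array."""
        if self.state_list is not None:
            return np.asarray(self.state_list, dtype=float)
        return np.arange(self.truncation_size, dtype=float)


@dataclass(frozen=True)
class MassAction:
    """Mass-action kinetics: ``rate * prod_i x_i (x_i-1) ... (x_i-nu_i+1)``.

    ``rate`` is a number or the name of a parameter / pseudo-species.
    """

    rate: RateRef

    def references(self) -> set[str]:
        return {self.rate} if isinstance(self.rate, str) else set()


@dataclass(frozen=True)
class Hill:
    """Hill-type regulation by a single species.

    ``activator`` mode gives ``vmax * x^n / (K^n + x^n)``; ``repressor`` mode
    gives ``vmax * K^n / (K^n + x^n)`` with ``x`` the regulator's count.
    """

    vmax: RateRef
    K: RateRef
    n: float
    regulator: str
    mode: str = "repressor"

    def __post_init__(self) -> None:
        if self.mode not in ("activator", "repressor"):
            raise ModelError(f"hill mode must be activator/repressor, got {self.mode!r}")

    def references(self) -> set[str]:
        refs = {self.regulator}
        for ref in (self.vmax, self.K):
            if isinstance(ref, str):
                refs.add(ref)
        return refs


@dataclass(frozen=True)
class LinearCombination:
    """Propensity ``sum_terms (c0 + sum_k theta_k) * x_species``.

    Each term is ``(coefficients, species_name_or_None)``: the coefficients
    (numbers and/or parameter names) are summed and multiplied by the named
    species' count (or by 1 when the species is ``None``).  This covers
    state-dependent transcription rates such as
    ``kp1 * G1 + (kp1 + kp2) * G2``.
    """

    terms: tuple[tuple[tuple[RateRef, ...], str | None], ...]

    def references(self) -> set[str]:
        refs: set[str] = set()
        for coeffs, sp in self.terms:
            if sp is not None:
                refs.add(sp)
            for c in coeffs:
                if isinstance(c, str):
                    refs.add(c)
        return refs


PropensityKinetics = Union[MassAction, Hill, LinearCombination]


@dataclass(frozen=True)
class Reaction:
    """A reaction with reactant/product stoichiometries and kinetics."""

    reactants: Mapping[str, int]
    products: Mapping[str, int]
    propensity: PropensityKinetics

    def __post_init__(self) -> None:
        for stoich in (self.reactants, self.products):
            for name, nu in stoich.items():
                if int(nu) < 0:
                    raise ModelError(f"negative stoichiometry for {name!r}")
        object.__setattr__(self, "reactants", dict(self.reactants))
        object.__setattr__(self, "products", dict(self.products))

    def net_change(self, names: Sequence[str]) -> np.ndarray:
        """Net state change ``zeta = nu' - nu`` ordered by ``names``."""
        zeta = np.zeros(len(names), dtype=np.int64)
        for i, name in enumerate(names):
            zeta[i] = self.products.get(name, 0) - self.reactants.get(name, 0)
        return zeta

    def dependencies(self) -> set[str]:
        """Names (species or parameters) the propensity may depend on.

        Reactant species are always included: their counts gate the firing
        even for non-mass-action kinetics.
        """
        deps = {n for n, nu in self.reactants.items() if nu > 0}
        return deps | self.propensity.references()


@dataclass(frozen=True)
class ParameterSpec:
    """A rate parameter restricted to a finite grid with a prior."""

    name: str
    grid: tuple[float, ...]
    prior: tuple[float, ...]

    def __post_init__(self) -> None:
        grid = tuple(float(g) for g in self.grid)
        prior = tuple(float(p) for p in self.prior)
        if len(grid) != len(prior):
            raise ModelError(f"parameter {self.name!r}: grid/prior length mismatch")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ModelError(f"parameter {self.name!r}: grid must be strictly increasing")
        if any(p < 0 for p in prior):
            raise ModelError(f"parameter {self.name!r}: negative prior mass")
        if abs(sum(prior) - 1.0) > 1e-12:
            raise ModelError(f"parameter {self.name!r}: prior must sum to 1")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "prior", prior)


# ---------------------------------------------------------------------------
# initial distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Marginal:
    """Per-component initial marginal: point mass, Poisson, or categorical."""

    kind: str  # "point" | "poisson" | "categorical"
    value: float = 0.0
    mean: float = 0.0
    values: tuple[float, ...] = ()
    probs: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("point", "poisson", "categorical"):
            raise ModelError(f"unknown marginal kind {self.kind!r}")
        if self.kind == "categorical":
            if len(self.values) != len(self.probs) or not self.values:
                raise ModelError("categorical marginal needs matching values/probs")
            if abs(sum(self.probs) - 1.0) > 1e-9:
                raise ModelError("categorical marginal probs must sum to 1")

    def pmf_on(self, values: np.ndarray) -> np.ndarray:
        """Probability mass on the given admissible values (unnormalized tail
        loss is renormalized away)."""
        values = np.asarray(values, dtype=float)
        if self.kind == "point":
            p = (values == float(self.value)).astype(float)
        elif self.kind == "poisson":
            from scipy.stats import poisson

            p = np.where(values >= 0, poisson.pmf(np.round(values), self.mean), 0.0)
        else:
            p = np.zeros(len(values))
            for v, q in zip(self.values, self.probs):
                idx = np.nonzero(values == float(v))[0]
                if idx.size:
                    p[idx[0]] += q
        total = p.sum()
        if total <= 0:
            raise ModelError("initial marginal has no mass on the truncation")
        return p / total

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "point":
            return float(self.value)
        if self.kind == "poisson":
            return float(rng.poisson(self.mean))
        i = rng.choice(len(self.values), p=np.asarray(self.probs))
        return float(self.values[i])


@dataclass(frozen=True)
class InitialDistribution:
    """Initial law: a product of per-component marginals or an explicit table.

    The explicit table maps full state tuples (component order of the owning
    network) to probabilities.
    """

    marginals: Mapping[str, Marginal] | None = None
    table: Mapping[tuple, float] | None = None

    def __post_init__(self) -> None:
        if (self.marginals is None) == (self.table is None):
            raise ModelError("initial distribution needs marginals XOR an explicit table")
        if self.marginals is not None:
            object.__setattr__(self, "marginals", dict(self.marginals))
        else:
            total = sum(self.table.values())
            if abs(total - 1.0) > 1e-9 or any(p < 0 for p in self.table.values()):
                raise ModelError("explicit initial table must be a probability table")
            object.__setattr__(self, "table", dict(self.table))

    @staticmethod
    def point(state: Mapping[str, float]) -> "InitialDistribution":
        return InitialDistribution(
            marginals={n: Marginal("point", value=v) for n, v in state.items()}
        )

    @staticmethod
    def product_poisson(means: Mapping[str, float]) -> "InitialDistribution":
        return InitialDistribution(
            marginals={n: Marginal("poisson", mean=m) for n, m in means.items()}
        )

    def marginal_for(self, name: str) -> Marginal:
        if self.marginals is None or name not in self.marginals:
            raise ModelError(f"no initial marginal declared for component {name!r}")
        return self.marginals[name]

    def sample_state(self, network: "ReactionNetwork", rng: np.random.Generator) -> np.ndarray:
        """Draw one full state vector."""
        if self.marginals is not None:
            return np.array(
                [self.marginal_for(sp.name).sample(rng) for sp in network.species], dtype=float
            )
        keys = list(self.table.keys())
        probs = np.array([self.table[k] for k in keys])
        i = rng.choice(len(keys), p=probs / probs.sum())
        return np.asarray(keys[i], dtype=float)


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------


@dataclass(frozen=True, eq=False)
class ReactionNetwork:
    """A validated reaction network.

    ``pseudo_param_specs`` is non-empty only on parameter-augmented networks,
    where the trailing species are static parameter pseudo-species whose
    admissible values are the parameter grids.
    """

    species: tuple[Species, ...]
    reactions: tuple[Reaction, ...]
    parameters: tuple[ParameterSpec, ...] = ()
    initial: InitialDistribution | None = None
    pseudo_param_specs: tuple[ParameterSpec, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "reactions", tuple(self.reactions))
        object.__setattr__(self, "parameters", tuple(self.parameters))
        object.__setattr__(self, "pseudo_param_specs", tuple(self.pseudo_param_specs))
        names = [sp.name for sp in self.species]
        if len(set(names)) != len(names):
            raise ModelError("duplicate species name")
        declared = set(names) | {p.name for p in self.parameters}
        for j, rxn in enumerate(self.reactions):
            for name in set(rxn.reactants) | set(rxn.products):
                if name not in names:
                    raise ModelError(f"reaction {j}: unknown species {name!r}")
            for ref in rxn.propensity.references():
                if ref not in declared:
                    raise ModelError(f"reaction {j}: undeclared reference {ref!r}")
            prop = rxn.propensity
            if isinstance(prop, MassAction) and not isinstance(prop.rate, str):
                if float(prop.rate) < 0:
                    raise ModelError(f"reaction {j}: negative rate constant")

    # --- basic queries -----------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.species)

    @property
    def r(self) -> int:
        return len(self.reactions)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(sp.name for sp in self.species)

    @property
    def pseudo_params(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.pseudo_param_specs)

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ModelError(f"unknown component {name!r}") from None

    def species_by_name(self, name: str) -> Species:
        return self.species[self.index_of(name)]

    @property
    def zeta(self) -> np.ndarray:
        """Stoichiometric net-change matrix of shape ``(r, n)``."""
        return np.array([rxn.net_change(self.names) for rxn in self.reactions], dtype=np.int64)

    def summary(self) -> dict:
        return {"n": self.n, "r": self.r, "zeta": self.zeta}

    def validate_theta(self, theta: Mapping[str, float] | None) -> dict[str, float]:
        """Check parameter values lie on their grids; returns a plain dict."""
        theta = dict(theta or {})
        for spec in self.parameters:
            if spec.name not in theta:
                raise ModelError(f"missing value for parameter {spec.name!r}")
            val = float(theta[spec.name])
            if not any(math.isclose(val, g, rel_tol=0.0, abs_tol=1e-12) for g in spec.grid):
                raise ModelError(f"parameter {spec.name!r} value {val} is off-grid")
        return theta


def build_network(
    species: Sequence[Species],
    reactions: Sequence[Reaction],
    params: Sequence[ParameterSpec] = (),
    init: InitialDistribution | None = None,
) -> ReactionNetwork:
    """Validate and assemble a :class:`ReactionNetwork`."""
    return ReactionNetwork(tuple(species), tuple(reactions), tuple(params), init)


def propensity_eval(
    network: ReactionNetwork,
    state: Sequence[float] | Mapping[str, float],
    theta: Mapping[str, float] | None = None,
    check: bool = True,
) -> np.ndarray:
    """Evaluate all reaction propensities at ``state``.

    ``state`` may be a vector in species order or a name->value mapping.
    ``theta`` supplies values for declared (non-augmented) parameters and is
    validated against the grids when ``check`` is true.
    """
    from . import engine

    if isinstance(state, Mapping):
        x = np.array([float(state[name]) for name in network.names])
    else:
        x = np.asarray(state, dtype=float)
        if x.shape != (network.n,):
            raise ModelError(f"state must have length {network.n}")
    if check:
        for sp, v in zip(network.species, x):
            vals = sp.values
            if not np.any(np.isclose(vals, v, rtol=0.0, atol=1e-12)):
                raise ModelError(f"state value {v} outside admissible range of {sp.name!r}")
        theta = network.validate_theta(theta) if network.parameters else dict(theta or {})
    enc = engine.compile_network(network, theta)
    lam = engine.eval_propensities(enc, x[None, :])[0]
    if not np.all(np.isfinite(lam)):
        raise ModelError("propensity evaluated non-finite")
    if np.any(lam < 0):
        raise ModelError("propensity evaluated negative")
    return lam


def augment_with_parameters(network: ReactionNetwork) -> ReactionNetwork:
    """Turn gridded parameters into static pseudo-species.

    The pseudo-species are appended after the chemical species, each with its
    grid as explicit state list and zero net change in every reaction; the
    initial law gains their priors as categorical marginals.  The augmented
    chain's marginal over the chemical species is unchanged.
    """
    if not network.parameters:
        raise ModelError("network has no parameters to augment")
    if network.initial is not None and network.initial.marginals is None:
        raise ModelError("augmentation requires a product-form initial distribution")
    pseudo = tuple(
        Species(spec.name, state_list=spec.grid) for spec in network.parameters
    )
    marginals = dict(network.initial.marginals) if network.initial is not None else {}
    for spec in network.parameters:
        marginals[spec.name] = Marginal("categorical", values=spec.grid, probs=spec.prior)
    init = InitialDistribution(marginals=marginals) if marginals else None
    return ReactionNetwork(
        species=network.species + pseudo,
        reactions=network.reactions,
        parameters=(),
        initial=init,
        pseudo_param_specs=network.parameters,
    )


# ---------------------------------------------------------------------------
# JSON model files
# ---------------------------------------------------------------------------


def _kinetics_to_json(kin: PropensityKinetics) -> dict:
    if isinstance(kin, MassAction):
        return {"kind": "mass_action", "rate": kin.rate}
    if isinstance(kin, Hill):
        return {
            "kind": "hill",
            "vmax": kin.vmax,
            "K": kin.K,
            "n": kin.n,
            "regulator": kin.regulator,
            "mode": kin.mode,
        }
    return {
        "kind": "linear_combination",
        "terms": [{"coeffs": list(coeffs), "species": sp} for coeffs, sp in kin.terms],
    }


def _kinetics_from_json(d: Mapping) -> PropensityKinetics:
    kind = d["kind"]
    if kind == "mass_action":
        return MassAction(rate=d["rate"])
    if kind == "hill":
        return Hill(vmax=d["vmax"], K=d["K"], n=d["n"], regulator=d["regulator"], mode=d["mode"])
    if kind == "linear_combination":
        return LinearCombination(
            terms=tuple((tuple(t["coeffs"]), t["species"]) for t in d["terms"])
        )
    raise ModelError(f"unknown kinetics kind {kind!r}")


def network_to_json(network: ReactionNetwork) -> str:
    """Serialize a network (species, reactions, parameters, initial) to JSON."""
    doc: dict = {
        "species": [
            {
                "name": sp.name,
                "truncation_size": sp.truncation_size,
                **({"state_list": list(sp.state_list)} if sp.state_list is not None else {}),
            }
            for sp in network.species
        ],
        "reactions": [
            {
                "reactants": dict(rxn.reactants),
                "products": dict(rxn.products),
                "kinetics": _kinetics_to_json(rxn.propensity),
            }
            for rxn in network.reactions
        ],
        "parameters": [
            {"name": p.name, "grid": list(p.grid), "prior": list(p.prior)}
            for p in network.parameters
        ],
    }
    if network.initial is not None:
        init = network.initial
        if init.marginals is not None:
            doc["initial"] = {
                "marginals": {
                    n: {
                        "kind": m.kind,
                        "value": m.value,
                        "mean": m.mean,
                        "values": list(m.values),
                        "probs": list(m.probs),
                    }
                    for n, m in init.marginals.items()
                }
            }
        else:
            doc["initial"] = {
                "table": [[list(k), v] for k, v in init.table.items()]
            }
    if network.pseudo_param_specs:
        doc["pseudo_parameters"] = [p.name for p in network.pseudo_param_specs]
    return json.dumps(doc, indent=1)


def network_from_json(text: str) -> ReactionNetwork:
    doc = json.loads(text)
    species = tuple(
        Species(
            d["name"],
            truncation_size=d.get("truncation_size", 0),
            state_list=tuple(d["state_list"]) if "state_list" in d else None,
        )
        for d in doc["species"]
    )
    reactions = tuple(
        Reaction(d["reactants"], d["products"], _kinetics_from_json(d["kinetics"]))
        for d in doc["reactions"]
    )
    params = tuple(
        ParameterSpec(d["name"], tuple(d["grid"]), tuple(d["prior"]))
        for d in doc.get("parameters", [])
    )
    init = None
    if "initial" in doc:
        d = doc["initial"]
        if "marginals" in d:
            init = InitialDistribution(
                marginals={
                    n: Marginal(
                        m["kind"],
                        value=m.get("value", 0.0),
                        mean=m.get("mean", 0.0),
                        values=tuple(m.get("values", ())),
                        probs=tuple(m.get("probs", ())),
                    )
                    for n, m in d["marginals"].items()
                }
            )
        else:
            init = InitialDistribution(table={tuple(k): v for k, v in d["table"]})
    net = ReactionNetwork(species, reactions, params, init)
    pseudo_names = doc.get("pseudo_parameters", [])
    if pseudo_names:
        # reconstruct pseudo-parameter marker from the stored names
        specs = []
        marg = net.initial.marginals if net.initial else {}
        for name in pseudo_names:
            sp = net.species_by_name(name)
            m = marg.get(name)
            prior = m.probs if m is not None else tuple([1.0 / sp.truncation_size] * sp.truncation_size)
            specs.append(ParameterSpec(name, tuple(sp.state_list), tuple(prior)))
        net = replace(net, pseudo_param_specs=tuple(specs))
    return net
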