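"""Array (compiled) form of a reaction network for the SSA and ODE engines."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import ReactionNetwork, effective_constant

MASS_ACTION = 0
HILL = 1


@dataclass
class CompiledNetwork:
    """Flat-array view of a network; shared by the SSA and ODE engines.

    Propensity factors (reactants + modifiers) are stored sparsely as CSR-style
    index/weight arrays; ``net`` is the dense net-stoichiometry matrix
    (reactions × species).
    """

    species: list[str]
    index: dict[str, int]
    c_eff: np.ndarray          # (R,) effective stochastic rate constants
    prop_ptr: np.ndarray       # (R+1,) CSR pointers into prop_species/prop_order
    prop_species: np.ndarray   # flattened species indices of propensity factors
    prop_order: np.ndarray     # factor order (1 or 2) per entry
    react_ptr: np.ndarray      # reactant-requirement CSR (for hill reactions)
    react_species: np.ndarray
    react_need: np.ndarray
    kind: np.ndarray           # (R,) MASS_ACTION or HILL
    hill_idx: np.ndarray       # (R,) species index of the Hill variable (or -1)
    hill_K: np.ndarray
    hill_n: np.ndarray
    net: np.ndarray            # (R, S) int64 net stoichiometry
    prop_W: np.ndarray         # (R, S) float64 dense propensity orders (mean field)
    x0: np.ndarray             # (S,) int64 initial copies

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return self.net.shape[0]


def compile_network(network: ReactionNetwork) -> CompiledNetwork:
    species = network.species_names
    index = {name: i for i, name in enumerate(species)}
    R, S = len(network.reactions), len(species)

    c_eff = np.zeros(R)
    kind = np.zeros(R, dtype=np.int8)
    hill_idx = np.full(R, -1, dtype=np.int64)
    hill_K = np.zeros(R)
    hill_n = np.ones(R)
    net = np.zeros((R, S), dtype=np.int64)

    prop_ptr = [0]
    prop_species: list[int] = []
    prop_order: list[int] = []
    react_ptr = [0]
    react_species: list[int] = []
    react_need: list[int] = []

    for r, rxn in enumerate(network.reactions):
        c_eff[r] = effective_constant(rxn, network)
        for name, n in rxn.reactants.items():
            net[r, index[name]] -= n
            react_species.append(index[name])
            react_need.append(n)
        react_ptr.append(len(react_species))
        for name, n in rxn.products.items():
            net[r, index[name]] += n
        if rxn.rate_law.kind == "hill_switch":
            kind[r] = HILL
            hill_idx[r] = index[rxn.rate_law.hill_species]
            hill_K[r] = network.parameters.get(rxn.rate_law.hill_K)
            hill_n[r] = network.parameters.get(rxn.rate_law.hill_n)
        else:
            for name, n in {**rxn.reactants, **rxn.modifiers}.items():
                prop_species.append(index[name])
                prop_order.append(n)
        prop_ptr.append(len(prop_species))

    prop_W = np.zeros((R, S))
    for r, rxn in enumerate(network.reactions):
        if rxn.rate_law.kind == "mass_action":
            for name, n in {**rxn.reactants, **rxn.modifiers}.items():
                prop_W[r, index[name]] = n

    x0 = np.array([s.initial_copies for s in network.species], dtype=np.int64)
    return CompiledNetwork(
        species=species,
        index=index,
        c_eff=c_eff,
        prop_ptr=np.asarray(prop_ptr, dtype=np.int64),
        prop_species=np.asarray(prop_species, dtype=np.int64),
        prop_order=np.asarray(prop_order, dtype=np.int64),
        react_ptr=np.asarray(react_ptr, dtype=np.int64),
        react_species=np.asarray(react_species, dtype=np.int64),
        react_need=np.asarray(react_need, dtype=np.int64),
        kind=kind,
        hill_idx=hill_idx,
        hill_K=hill_K,
        hill_n=hill_n,
        net=net,
        prop_W=prop_W,
        x0=x0,
    )


def deterministic_rates(compiled: CompiledNetwork, x: np.ndarray) -> np.ndarray:
    """Mean-field rate vector v(x): large-copy limit of the propensities.

    Mass action uses plain powers (x², not x·(x−1)); the Hill switch keeps the
    same functional form with continuous x clipped at zero.
    """
    xc = np.maximum(x, 0.0)
    v = compiled.c_eff * np.prod(xc[None, :] ** compiled.prop_W, axis=1)
    hill_rows = np.flatnonzero(compiled.kind == HILL)
    for r in hill_rows:
        xi = xc[compiled.hill_idx[r]]
        K, n = compiled.hill_K[r], compiled.hill_n[r]
        v[r] = compiled.c_eff[r] * xi * xi**n / (K**n + xi**n)
    return v


def rhs(compiled: CompiledNetwork, x: np.ndarray) -> np.ndarray:
    """dx/dt = Sᵀ·v(x) for the mean-field ODE."""
    return compiled.net.T @ deterministic_rates(compiled, x)
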