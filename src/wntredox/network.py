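"""Intracellular Wnt/β-catenin + redox reaction network.

The model describes a cell without any extracellular Wnt stimulus: β-catenin is
continuously synthesized and degraded by the AXIN-scaffolded destruction
complex. Oxidative stress (a dimensionless ROS input) releases Dishevelled
(DVL) from its redox-sensitive complex with Nucleoredoxin (NRX); free DVL
self-aggregates once it passes a concentration threshold, and the aggregates
sequester AXIN, inhibiting β-catenin degradation. Nuclear β-catenin binds
TCF to form the transcriptionally active TCF/β-catenin complex, which drives
a lumped target-protein reporter and (as the AXIN2 negative feedback) AXIN
production. Two inhibitors shape the transcriptional output: ICAT reversibly
binds β-catenin in both compartments (no degradation), and nuclear SOX17
catalytically targets the whole TCF/β-catenin complex for proteasomal
degradation, independent of the destruction complex.

Units are molecules per cell and hours. Copy numbers are integers (the network
is a continuous-time Markov chain); bimolecular rate constants are divided by
the volume fraction of the compartment the reaction takes place in.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import yaml

from .errors import ConfigurationError, InvariantViolation, ScopeError

__all__ = [
    "Species",
    "Compartment",
    "RateLaw",
    "Reaction",
    "ParameterSet",
    "ConservationGroup",
    "ReactionNetwork",
    "DVL_AGG_MONOMERS",
    "SCALABLE_GENES",
    "default_parameters",
    "build_network",
    "propensity",
    "apply_scenario_scaling",
    "check_network",
    "network_to_yaml",
    "network_from_yaml",
    "network_to_sbml",
]

#: Number of DVL monomers consumed per aggregate (bookkeeping for conservation).
DVL_AGG_MONOMERS = 2

#: Genes whose mRNA fold changes may be applied as synthesis-rate multipliers.
#: Membrane/secretion components (WLS, SOST, SFRP4, receptors) are outside the
#: intracellular model scope by construction.
SCALABLE_GENES = {
    "ICAT": "k_icat_syn",
    "SOX17": "k_sox_syn",
    "TCF": "k_tcf_syn",
}

CYTOSOL = "cytosol"
NUCLEUS = "nucleus"


@dataclass(frozen=True)
class Species:
    name: str
    compartment: str
    initial_copies: int

    def __post_init__(self) -> None:
        if self.initial_copies < 0 or int(self.initial_copies) != self.initial_copies:
            raise ConfigurationError(
                f"species {self.name!r}: initial_copies must be a non-negative "
                f"integer, got {self.initial_copies!r}"
            )


@dataclass(frozen=True)
class Compartment:
    name: str
    volume_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 < self.volume_fraction <= 1.0):
            raise ConfigurationError(
                f"compartment {self.name!r}: volume fraction must be in (0, 1], "
                f"got {self.volume_fraction}"
            )


@dataclass(frozen=True)
class RateLaw:
    """Kinetic law of a reaction.

    ``constant`` (and the Hill parameters) are *names* resolved against the
    network's :class:`ParameterSet`, so that a fitted parameter set can be
    swapped in without touching the reaction list.
    """

    kind: str  # "mass_action" | "hill_switch"
    constant: str
    hill_K: str | None = None
    hill_n: str | None = None
    hill_species: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("mass_action", "hill_switch"):
            raise ConfigurationError(f"unknown rate-law kind {self.kind!r}")
        if self.kind == "hill_switch" and not (
            self.hill_K and self.hill_n and self.hill_species
        ):
            raise ConfigurationError(
                "hill_switch rate law requires hill_K, hill_n and hill_species"
            )


@dataclass(frozen=True)
class Reaction:
    """One elementary reaction.

    ``modifiers`` enter the propensity (catalysts / template species) but are
    not changed by firing.  ``input_scale`` multiplies the rate constant by a
    network-level input: ``"ros"`` (the dimensionless ROS level) or
    ``"scaffold"`` (the constant APC/GSK3β/CK1 scaffold pool).
    """

    label: str
    group: str
    reactants: Mapping[str, int] = field(default_factory=dict)
    products: Mapping[str, int] = field(default_factory=dict)
    modifiers: Mapping[str, int] = field(default_factory=dict)
    rate_law: RateLaw = RateLaw("mass_action", "k")
    input_scale: str | None = None

    def __post_init__(self) -> None:
        for name, count in {**self.reactants, **self.products, **self.modifiers}.items():
            if count < 0 or int(count) != count:
                raise ConfigurationError(
                    f"reaction {self.label!r}: stoichiometry of {name!r} must be "
                    f"a non-negative integer"
                )
        if self.input_scale not in (None, "ros", "scaffold"):
            raise ConfigurationError(
                f"reaction {self.label!r}: unknown input scale {self.input_scale!r}"
            )

    @property
    def propensity_order(self) -> int:
        if self.rate_law.kind == "hill_switch":
            return 1
        return sum(self.reactants.values()) + sum(self.modifiers.values())


@dataclass
class ParameterSet:
    """Named rate constants (per-hour basis) plus the two scalar inputs."""

    values: dict[str, float]
    scaffold_pool: float = 100.0
    ros_baseline: float = 1.0

    def get(self, name: str) -> float:
        try:
            return self.values[name]
        except KeyError:
            raise ConfigurationError(f"missing parameter {name!r}") from None

    def copy(self) -> "ParameterSet":
        return ParameterSet(dict(self.values), self.scaffold_pool, self.ros_baseline)

    def validate(self) -> list[str]:
        problems = []
        import math

        for name, value in self.values.items():
            if not math.isfinite(value) or value < 0:
                problems.append(f"parameter {name!r} must be finite and >= 0, got {value}")
        if self.scaffold_pool < 0:
            problems.append("scaffold_pool must be >= 0")
        if self.ros_baseline < 0:
            problems.append("ros_baseline must be >= 0")
        return problems


@dataclass(frozen=True)
class ConservationGroup:
    """A weighted species total that every non-exempt reaction must conserve."""

    name: str
    weights: Mapping[str, int]
    exempt_labels: frozenset[str]


@dataclass
class ReactionNetwork:
    species: list[Species]
    reactions: list[Reaction]
    compartments: dict[str, Compartment]
    parameters: ParameterSet
    ros_input: float = 1.0
    flags: dict[str, bool] = field(default_factory=dict)
    conservation_groups: list[ConservationGroup] = field(default_factory=list)

    # -- convenience ------------------------------------------------------
    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def reaction_groups(self) -> list[str]:
        seen: list[str] = []
        for r in self.reactions:
            if r.group not in seen:
                seen.append(r.group)
        return seen

    def species_index(self) -> dict[str, int]:
        return {s.name: i for i, s in enumerate(self.species)}

    def get_species(self, name: str) -> Species:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)

    def initial_state(self) -> dict[str, int]:
        return {s.name: s.initial_copies for s in self.species}

    def copy(self) -> "ReactionNetwork":
        return ReactionNetwork(
            species=list(self.species),
            reactions=list(self.reactions),
            compartments=dict(self.compartments),
            parameters=self.parameters.copy(),
            ros_input=self.ros_input,
            flags=dict(self.flags),
            conservation_groups=list(self.conservation_groups),
        )

    def with_ros(self, level: float) -> "ReactionNetwork":
        if level < 0:
            raise ConfigurationError(f"ROS input must be >= 0, got {level}")
        net = self.copy()
        net.ros_input = float(level)
        return net

    def with_initial_copies(self, patches: Mapping[str, int]) -> "ReactionNetwork":
        net = self.copy()
        index = net.species_index()
        for name, copies in patches.items():
            if name not in index:
                raise ConfigurationError(f"unknown species {name!r}")
            net.species[index[name]] = replace(net.species[index[name]], initial_copies=int(copies))
        return net


# ---------------------------------------------------------------------------
# Default model definition
# ---------------------------------------------------------------------------

#: Calibrated default rate constants (per hour; bimolecular constants are per
#: molecule per hour before compartment volume scaling).  Backbone constants
#: (β-catenin turnover, shuttling, destruction-complex cycling, AXIN) follow
#: the classic cytosolic Wnt model rescaled to molecules per cell at an
#: assumed 2 pL cell volume; the extension constants (redox arm, ICAT, SOX17,
#: TCF) are calibration outputs (see wntredox.calibration and docs/methods.md).
DEFAULT_PARAM_VALUES: dict[str, float] = {
    # β-catenin backbone
    "k_bc_syn": 600.0,
    "k_bc_deg_dc": 0.07,
    "k_bc_deg_basal": 0.05,
    "k_bc_in": 0.8,
    "k_bc_out": 1.2,
    # destruction-complex cycling against the constant scaffold pool
    "k_dc_assemble": 0.05,
    "k_dc_disassemble": 5.0,
    # redox arm: NRX·DVL release, re-association, aggregation, AXIN capture
    "k_dvl_release": 0.05,
    "k_dvl_rebind": 1.0,
    "k_dvl_agg": 2.0,
    "dvl_agg_K": 50.0,
    "dvl_agg_n": 4.0,
    "k_dvl_disagg": 0.5,
    "k_dvl_axin_on": 0.5,
    "k_dvl_axin_off": 0.05,
    "k_axin_deg_dvl": 0.178,
    # nuclear TCF/β-catenin complex and transcription
    "k_tcf_on": 0.00152,
    "k_tcf_off": 1.0,
    "k_tx": 1.0,
    "k_target_deg": 0.25,
    "k_axin_fb": 3.5,
    # ICAT (CTNNBIP1)
    "k_icat_syn": 433.0,
    "k_icat_deg": 0.6,
    "k_icat_in": 3.36,
    "k_icat_out": 0.5,
    "k_icat_bc_on": 0.0151,
    "k_icat_bc_off": 1.49,
    "k_icatbc_export": 0.368,
    # SOX17
    "k_sox_syn": 15.0,
    "k_sox_deg": 0.5,
    "k_sox_tcfbc_deg": 0.0724,
    # TCF synthesis / turnover (turnover acts on free and complexed TCF alike)
    "k_tcf_syn": 30.0,
    "k_tcf_deg": 0.5,
    # AXIN basal turnover
    "k_axin_syn": 10.0,
    "k_axin_deg": 0.5,
}

#: Default initial copy numbers (reference-condition steady state, rounded).
DEFAULT_INITIAL_COPIES: dict[str, int] = {
    "BC_c": 196,
    "BC_n": 61,
    "AXIN": 30,
    "DC": 30,
    "NRX_DVL": 88,
    "DVL_free": 4,
    "DVL_agg": 0,
    "DVL_AXIN": 0,
    "ICAT_c": 109,
    "ICAT_n": 158,
    "ICATBC_c": 256,
    "ICATBC_n": 199,
    "TCF": 39,
    "TCFBC": 1,
    "SOX17": 30,
    "TargetProtein": 6,
}

SPECIES_COMPARTMENTS: dict[str, str] = {
    "BC_c": CYTOSOL,
    "BC_n": NUCLEUS,
    "AXIN": CYTOSOL,
    "DC": CYTOSOL,
    "NRX_DVL": CYTOSOL,
    "DVL_free": CYTOSOL,
    "DVL_agg": CYTOSOL,
    "DVL_AXIN": CYTOSOL,
    "ICAT_c": CYTOSOL,
    "ICAT_n": NUCLEUS,
    "ICATBC_c": CYTOSOL,
    "ICATBC_n": NUCLEUS,
    "TCF": NUCLEUS,
    "TCFBC": NUCLEUS,
    "SOX17": NUCLEUS,
    "TargetProtein": CYTOSOL,
}

DEFAULT_COMPARTMENTS = {
    CYTOSOL: Compartment(CYTOSOL, 0.7),
    NUCLEUS: Compartment(NUCLEUS, 0.3),
}

#: Feature flags and their defaults.
DEFAULT_FLAGS: dict[str, bool] = {
    "feedback": True,               # R11c: TCF/β-catenin-driven AXIN production (AXIN2)
    "icat_export": True,            # R14: enhanced nuclear export of the ICAT·β-catenin complex
    "sox17_codegradation": True,    # R16: SOX17-catalysed TCF/β-catenin co-degradation
    "icat_cytosolic_binding": True, # R13a/b: ICAT binds β-catenin in the cytosol too
}


def default_parameters() -> ParameterSet:
    """Fresh copy of the calibrated default parameter set."""
    return ParameterSet(dict(DEFAULT_PARAM_VALUES), scaffold_pool=100.0, ros_baseline=1.0)


def _ma(label, group, reactants, products, constant, modifiers=None, input_scale=None):
    return Reaction(
        label=label,
        group=group,
        reactants=dict(reactants),
        products=dict(products),
        modifiers=dict(modifiers or {}),
        rate_law=RateLaw("mass_action", constant),
        input_scale=input_scale,
    )


def _reaction_table(flags: Mapping[str, bool]) -> list[Reaction]:
    rxns: list[Reaction] = [
        # β-catenin synthesis and degradation
        _ma("R1", "R1", {}, {"BC_c": 1}, "k_bc_syn"),
        _ma("R2", "R2", {"BC_c": 1}, {}, "k_bc_deg_dc", modifiers={"DC": 1}),
        _ma("R3", "R3", {"BC_c": 1}, {}, "k_bc_deg_basal"),
        # nucleo-cytoplasmic shuttling
        _ma("R4a", "R4", {"BC_c": 1}, {"BC_n": 1}, "k_bc_in"),
        _ma("R4b", "R4", {"BC_n": 1}, {"BC_c": 1}, "k_bc_out"),
        # destruction-complex cycling (AXIN rate-limiting; scaffold pool constant)
        _ma("R5a", "R5", {"AXIN": 1}, {"DC": 1}, "k_dc_assemble", input_scale="scaffold"),
        _ma("R5b", "R5", {"DC": 1}, {"AXIN": 1}, "k_dc_disassemble"),
        # redox arm
        _ma("R6", "R6", {"NRX_DVL": 1}, {"DVL_free": 1}, "k_dvl_release", input_scale="ros"),
        _ma("R7", "R7", {"DVL_free": 1}, {"NRX_DVL": 1}, "k_dvl_rebind"),
        Reaction(
            label="R8a",
            group="R8",
            reactants={"DVL_free": DVL_AGG_MONOMERS},
            products={"DVL_agg": 1},
            rate_law=RateLaw(
                "hill_switch", "k_dvl_agg",
                hill_K="dvl_agg_K", hill_n="dvl_agg_n", hill_species="DVL_free",
            ),
        ),
        _ma("R8b", "R8", {"DVL_agg": 1}, {"DVL_free": DVL_AGG_MONOMERS}, "k_dvl_disagg"),
        _ma("R9a", "R9", {"DVL_agg": 1, "AXIN": 1}, {"DVL_AXIN": 1}, "k_dvl_axin_on"),
        _ma("R9b", "R9", {"DVL_AXIN": 1}, {"DVL_agg": 1, "AXIN": 1}, "k_dvl_axin_off"),
        # AXIN turnover on the DVL platform: DVL recruitment channels AXIN to
        # degradation, so ROS-driven sequestration depletes the free AXIN pool
        # at steady state rather than merely re-partitioning it
        _ma("R9c", "R9", {"DVL_AXIN": 1}, {"DVL_agg": 1}, "k_axin_deg_dvl"),
        # TCF/β-catenin complex
        _ma("R10a", "R10", {"BC_n": 1, "TCF": 1}, {"TCFBC": 1}, "k_tcf_on"),
        _ma("R10b", "R10", {"TCFBC": 1}, {"BC_n": 1, "TCF": 1}, "k_tcf_off"),
        # target-gene expression (lumped reporter) and AXIN2 feedback
        _ma("R11a", "R11", {}, {"TargetProtein": 1}, "k_tx", modifiers={"TCFBC": 1}),
        _ma("R11b", "R11", {"TargetProtein": 1}, {}, "k_target_deg"),
    ]
    if flags["feedback"]:
        rxns.append(_ma("R11c", "R11", {}, {"AXIN": 1}, "k_axin_fb", modifiers={"TCFBC": 1}))
    # ICAT synthesis, turnover (same first-order rate for free and β-catenin-
    # bound ICAT; complex decay releases β-catenin) and shuttling
    rxns += [
        _ma("R12a", "R12", {}, {"ICAT_c": 1}, "k_icat_syn"),
        _ma("R12b", "R12", {"ICAT_c": 1}, {}, "k_icat_deg"),
        _ma("R12c", "R12", {"ICAT_c": 1}, {"ICAT_n": 1}, "k_icat_in"),
        _ma("R12d", "R12", {"ICAT_n": 1}, {"ICAT_c": 1}, "k_icat_out"),
        _ma("R12e", "R12", {"ICAT_n": 1}, {}, "k_icat_deg"),
        _ma("R12f", "R12", {"ICATBC_c": 1}, {"BC_c": 1}, "k_icat_deg"),
        _ma("R12g", "R12", {"ICATBC_n": 1}, {"BC_n": 1}, "k_icat_deg"),
    ]
    # ICAT·β-catenin binding (reversible, no β-catenin degradation)
    if flags["icat_cytosolic_binding"]:
        rxns += [
            _ma("R13a", "R13", {"ICAT_c": 1, "BC_c": 1}, {"ICATBC_c": 1}, "k_icat_bc_on"),
            _ma("R13b", "R13", {"ICATBC_c": 1}, {"ICAT_c": 1, "BC_c": 1}, "k_icat_bc_off"),
        ]
    rxns += [
        _ma("R13c", "R13", {"ICAT_n": 1, "BC_n": 1}, {"ICATBC_n": 1}, "k_icat_bc_on"),
        _ma("R13d", "R13", {"ICATBC_n": 1}, {"ICAT_n": 1, "BC_n": 1}, "k_icat_bc_off"),
    ]
    if flags["icat_export"]:
        rxns.append(_ma("R14", "R14", {"ICATBC_n": 1}, {"ICATBC_c": 1}, "k_icatbc_export"))
    rxns += [
        _ma("R15a", "R15", {}, {"SOX17": 1}, "k_sox_syn"),
        _ma("R15b", "R15", {"SOX17": 1}, {}, "k_sox_deg"),
    ]
    if flags["sox17_codegradation"]:
        # catalytic: SOX17 targets the whole complex for proteasomal degradation
        rxns.append(_ma("R16", "R16", {"TCFBC": 1}, {}, "k_sox_tcfbc_deg", modifiers={"SOX17": 1}))
    rxns += [
        # TCF synthesis and turnover (turnover also acts on complexed TCF,
        # releasing β-catenin)
        _ma("R17a", "R17", {}, {"TCF": 1}, "k_tcf_syn"),
        _ma("R17b", "R17", {"TCF": 1}, {}, "k_tcf_deg"),
        _ma("R17c", "R17", {"TCFBC": 1}, {"BC_n": 1}, "k_tcf_deg"),
        # AXIN basal turnover
        _ma("R18a", "R18", {}, {"AXIN": 1}, "k_axin_syn"),
        _ma("R18b", "R18", {"AXIN": 1}, {}, "k_axin_deg"),
    ]
    return rxns


def _conservation_groups(flags: Mapping[str, bool]) -> list[ConservationGroup]:
    m = DVL_AGG_MONOMERS
    return [
        ConservationGroup(
            "DVL",
            {"NRX_DVL": 1, "DVL_free": 1, "DVL_agg": m, "DVL_AXIN": m},
            exempt_labels=frozenset(),  # nothing may create or destroy DVL monomers
        ),
        ConservationGroup(
            "TCF",
            {"TCF": 1, "TCFBC": 1},
            exempt_labels=frozenset({"R17a", "R17b", "R17c", "R16"}),
        ),
        ConservationGroup(
            "ICAT",
            {"ICAT_c": 1, "ICAT_n": 1, "ICATBC_c": 1, "ICATBC_n": 1},
            exempt_labels=frozenset({"R12a", "R12b", "R12e", "R12f", "R12g"}),
        ),
        ConservationGroup(
            "BC",
            {"BC_c": 1, "BC_n": 1, "ICATBC_c": 1, "ICATBC_n": 1, "TCFBC": 1},
            exempt_labels=frozenset({"R1", "R2", "R3", "R16"}),
        ),
    ]


def build_network(
    params: ParameterSet | None = None,
    options: Mapping[str, bool] | None = None,
) -> ReactionNetwork:
    """Build and validate the full model network.

    Parameters
    ----------
    params
        Rate constants and scalar inputs; defaults to the calibrated set.
    options
        Feature flags (see ``DEFAULT_FLAGS``): ``feedback``, ``icat_export``,
        ``sox17_codegradation``, ``icat_cytosolic_binding``. Unknown keys
        raise :class:`ConfigurationError`.
    """
    params = params.copy() if params is not None else default_parameters()
    flags = dict(DEFAULT_FLAGS)
    for key, value in (options or {}).items():
        if key not in DEFAULT_FLAGS:
            raise ConfigurationError(
                f"unknown feature flag {key!r}; known flags: {sorted(DEFAULT_FLAGS)}"
            )
        flags[key] = bool(value)

    reactions = _reaction_table(flags)

    # every referenced rate constant must resolve
    for rxn in reactions:
        for name in filter(None, (rxn.rate_law.constant, rxn.rate_law.hill_K, rxn.rate_law.hill_n)):
            if name not in params.values:
                raise ConfigurationError(f"missing parameter {name!r} (reaction {rxn.label})")

    species = [
        Species(name, SPECIES_COMPARTMENTS[name], DEFAULT_INITIAL_COPIES[name])
        for name in SPECIES_COMPARTMENTS
    ]
    net = ReactionNetwork(
        species=species,
        reactions=reactions,
        compartments=dict(DEFAULT_COMPARTMENTS),
        parameters=params,
        ros_input=params.ros_baseline,
        flags=flags,
        conservation_groups=_conservation_groups(flags),
    )
    violations = check_network(net)
    if violations:
        raise ConfigurationError("invalid network: " + "; ".join(violations))
    return net


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------

def reaction_compartment(reaction: Reaction, network: ReactionNetwork) -> str | None:
    """Compartment of a reaction's propensity factors (None for zero-order)."""
    comps = {
        SPECIES_LOOKUP(network)[name]
        for name in list(reaction.reactants) + list(reaction.modifiers)
    }
    if not comps:
        return None
    if len(comps) > 1:
        # cross-compartment bimolecular steps are not allowed in this model
        return "__mixed__"
    return comps.pop()


def SPECIES_LOOKUP(network: ReactionNetwork) -> dict[str, str]:
    return {s.name: s.compartment for s in network.species}


def effective_constant(reaction: Reaction, network: ReactionNetwork) -> float:
    """Stochastic rate constant after input scaling and volume correction."""
    c = network.parameters.get(reaction.rate_law.constant)
    if reaction.input_scale == "ros":
        c *= network.ros_input
    elif reaction.input_scale == "scaffold":
        c *= network.parameters.scaffold_pool
    if reaction.rate_law.kind == "mass_action" and reaction.propensity_order == 2:
        comp = reaction_compartment(reaction, network)
        c /= network.compartments[comp].volume_fraction
    return c


def propensity(
    state: Mapping[str, int],
    reaction: Reaction,
    network: ReactionNetwork,
) -> float:
    """CTMC propensity (events per hour) of ``reaction`` in ``state``.

    Mass action uses the stochastic falling-factorial form (order ≤ 2);
    the Hill switch models the DVL aggregation threshold as
    ``c·x·xⁿ/(Kⁿ + xⁿ)`` with ``x`` the free-DVL copy number. The propensity
    is zero whenever any reactant count is below its stoichiometric
    requirement.
    """
    copies = getattr(state, "copies", state)
    for name, count in copies.items():
        if count < 0:
            raise InvariantViolation(f"negative copy number: {name} = {count}")
    for name, need in reaction.reactants.items():
        if copies.get(name, 0) < need:
            return 0.0

    c = effective_constant(reaction, network)
    law = reaction.rate_law
    if law.kind == "hill_switch":
        x = float(copies.get(law.hill_species, 0))
        K = network.parameters.get(law.hill_K)
        n = network.parameters.get(law.hill_n)
        return c * x * x**n / (K**n + x**n)

    a = c
    for name, order in {**reaction.reactants, **reaction.modifiers}.items():
        x = copies.get(name, 0)
        if order == 1:
            a *= x
        elif order == 2:
            a *= x * (x - 1)
        else:  # pragma: no cover - excluded by validation
            raise ConfigurationError(
                f"reaction {reaction.label!r}: mass-action order > 2 unsupported"
            )
    return a


# ---------------------------------------------------------------------------
# Scenario scaling
# ---------------------------------------------------------------------------

def apply_scenario_scaling(
    network: ReactionNetwork, fold_map: Mapping[str, float]
) -> ReactionNetwork:
    """Scale zero-order synthesis rate constants by per-gene mRNA fold changes.

    Only the synthesis constants of ICAT, SOX17 and TCF can be scaled —
    membrane-associated Wnt components are outside the intracellular model
    scope and raise :class:`ScopeError`.
    """
    scaled = network.copy()
    for gene, multiplier in fold_map.items():
        if gene not in SCALABLE_GENES:
            raise ScopeError(
                f"{gene!r} is outside the intracellular model scope; "
                f"scalable genes: {sorted(SCALABLE_GENES)}"
            )
        if not multiplier > 0:
            raise ConfigurationError(
                f"fold multiplier for {gene!r} must be > 0, got {multiplier}"
            )
        key = SCALABLE_GENES[gene]
        scaled.parameters.values[key] = scaled.parameters.values[key] * float(multiplier)
    return scaled


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def check_network(network: ReactionNetwork) -> list[str]:
    """Validate the network; returns a list of violations (empty on success)."""
    violations: list[str] = []
    names = [s.name for s in network.species]
    if len(set(names)) != len(names):
        violations.append("duplicate species names")
    known = set(names)

    for s in network.species:
        if s.compartment not in network.compartments:
            violations.append(f"species {s.name!r}: unknown compartment {s.compartment!r}")

    total_vf = sum(c.volume_fraction for c in network.compartments.values())
    if total_vf > 1.0 + 1e-12:
        violations.append(f"compartment volume fractions sum to {total_vf} > 1")

    violations.extend(network.parameters.validate())

    for rxn in network.reactions:
        for name in (*rxn.reactants, *rxn.products, *rxn.modifiers):
            if name not in known:
                violations.append(f"reaction {rxn.label!r} references unknown species {name!r}")
        for pname in filter(
            None, (rxn.rate_law.constant, rxn.rate_law.hill_K, rxn.rate_law.hill_n)
        ):
            if pname not in network.parameters.values:
                violations.append(f"reaction {rxn.label!r}: missing parameter {pname!r}")
        if rxn.rate_law.kind == "mass_action" and rxn.propensity_order > 2:
            violations.append(f"reaction {rxn.label!r}: mass-action order > 2")
        if (
            rxn.rate_law.kind == "mass_action"
            and rxn.propensity_order == 2
            and reaction_compartment(rxn, network) == "__mixed__"
        ):
            violations.append(f"reaction {rxn.label!r}: bimolecular across compartments")
        if rxn.rate_law.kind == "hill_switch":
            K = network.parameters.values.get(rxn.rate_law.hill_K, -1.0)
            n = network.parameters.values.get(rxn.rate_law.hill_n, -1.0)
            if not K > 0:
                violations.append(f"reaction {rxn.label!r}: hill_K must be > 0")
            if not n >= 1:
                violations.append(f"reaction {rxn.label!r}: hill_n must be >= 1")

    # declared conservation relations: for every non-exempt reaction the
    # weighted net stoichiometry must vanish (a left-null-space condition)
    for group in network.conservation_groups:
        for rxn in network.reactions:
            if rxn.label in group.exempt_labels:
                continue
            delta = 0
            for name, w in group.weights.items():
                delta += w * (rxn.products.get(name, 0) - rxn.reactants.get(name, 0))
            if delta != 0:
                violations.append(
                    f"conservation group {group.name!r} broken by reaction "
                    f"{rxn.label!r} (weighted net change {delta:+d})"
                )
    return violations


# ---------------------------------------------------------------------------
# Serialization (YAML round trip; minimal SBML Level 3 export)
# ---------------------------------------------------------------------------

def network_to_dict(network: ReactionNetwork) -> dict:
    return {
        "compartments": [
            {"name": c.name, "volume_fraction": c.volume_fraction}
            for c in network.compartments.values()
        ],
        "species": [
            {"name": s.name, "compartment": s.compartment, "initial_copies": s.initial_copies}
            for s in network.species
        ],
        "reactions": [
            {
                "label": r.label,
                "group": r.group,
                "reactants": dict(r.reactants),
                "products": dict(r.products),
                "modifiers": dict(r.modifiers),
                "rate_law": {
                    "kind": r.rate_law.kind,
                    "constant": r.rate_law.constant,
                    **(
                        {
                            "hill_K": r.rate_law.hill_K,
                            "hill_n": r.rate_law.hill_n,
                            "hill_species": r.rate_law.hill_species,
                        }
                        if r.rate_law.kind == "hill_switch"
                        else {}
                    ),
                },
                **({"input_scale": r.input_scale} if r.input_scale else {}),
            }
            for r in network.reactions
        ],
        "parameters": {
            "values": dict(network.parameters.values),
            "scaffold_pool": network.parameters.scaffold_pool,
            "ros_baseline": network.parameters.ros_baseline,
        },
        "ros_input": network.ros_input,
        "flags": dict(network.flags),
        "conservation_groups": [
            {
                "name": g.name,
                "weights": dict(g.weights),
                "exempt_labels": sorted(g.exempt_labels),
            }
            for g in network.conservation_groups
        ],
    }


def network_from_dict(data: Mapping) -> ReactionNetwork:
    compartments = {
        c["name"]: Compartment(c["name"], float(c["volume_fraction"]))
        for c in data["compartments"]
    }
    species = [
        Species(s["name"], s["compartment"], int(s["initial_copies"]))
        for s in data["species"]
    ]
    reactions = []
    for r in data["reactions"]:
        law = r["rate_law"]
        reactions.append(
            Reaction(
                label=r["label"],
                group=r["group"],
                reactants={k: int(v) for k, v in (r.get("reactants") or {}).items()},
                products={k: int(v) for k, v in (r.get("products") or {}).items()},
                modifiers={k: int(v) for k, v in (r.get("modifiers") or {}).items()},
                rate_law=RateLaw(
                    law["kind"],
                    law["constant"],
                    hill_K=law.get("hill_K"),
                    hill_n=law.get("hill_n"),
                    hill_species=law.get("hill_species"),
                ),
                input_scale=r.get("input_scale"),
            )
        )
    pdata = data["parameters"]
    params = ParameterSet(
        {k: float(v) for k, v in pdata["values"].items()},
        scaffold_pool=float(pdata.get("scaffold_pool", 0.0)),
        ros_baseline=float(pdata.get("ros_baseline", 1.0)),
    )
    groups = [
        ConservationGroup(
            g["name"],
            {k: int(v) for k, v in g["weights"].items()},
            frozenset(g.get("exempt_labels", ())),
        )
        for g in data.get("conservation_groups", [])
    ]
    return ReactionNetwork(
        species=species,
        reactions=reactions,
        compartments=compartments,
        parameters=params,
        ros_input=float(data.get("ros_input", params.ros_baseline)),
        flags=dict(data.get("flags", {})),
        conservation_groups=groups,
    )


def network_to_yaml(network: ReactionNetwork, path=None) -> str:
    text = yaml.safe_dump(network_to_dict(network), sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def network_from_yaml(source) -> ReactionNetwork:
    """Load a network from a YAML string or file path."""
    import os

    if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
        with open(source) as fh:
            data = yaml.safe_load(fh)
    else:
        data = yaml.safe_load(source)
    return network_from_dict(data)


_SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
_MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def network_to_sbml(network: ReactionNetwork, path=None) -> str:
    """Minimal SBML Level 3 Version 1 export (species, reactions, kinetics)."""
    from xml.etree import ElementTree as ET

    ET.register_namespace("", _SBML_NS)
    sbml = ET.Element(f"{{{_SBML_NS}}}sbml", {"level": "3", "version": "1"})
    model = ET.SubElement(sbml, f"{{{_SBML_NS}}}model", {"id": "wnt_redox"})

    comps = ET.SubElement(model, f"{{{_SBML_NS}}}listOfCompartments")
    for c in network.compartments.values():
        ET.SubElement(
            comps,
            f"{{{_SBML_NS}}}compartment",
            {"id": c.name, "size": str(c.volume_fraction), "constant": "true",
             "spatialDimensions": "3"},
        )
    sps = ET.SubElement(model, f"{{{_SBML_NS}}}listOfSpecies")
    for s in network.species:
        ET.SubElement(
            sps,
            f"{{{_SBML_NS}}}species",
            {
                "id": s.name,
                "compartment": s.compartment,
                "initialAmount": str(s.initial_copies),
                "hasOnlySubstanceUnits": "true",
                "boundaryCondition": "false",
                "constant": "false",
            },
        )
    pars = ET.SubElement(model, f"{{{_SBML_NS}}}listOfParameters")
    extra = {
        "scaffold_pool": network.parameters.scaffold_pool,
        "ros_input": network.ros_input,
    }
    for name, value in {**network.parameters.values, **extra}.items():
        ET.SubElement(
            pars,
            f"{{{_SBML_NS}}}parameter",
            {"id": name, "value": str(value), "constant": "true"},
        )

    rxns = ET.SubElement(model, f"{{{_SBML_NS}}}listOfReactions")
    for r in network.reactions:
        rx = ET.SubElement(
            rxns, f"{{{_SBML_NS}}}reaction", {"id": r.label, "reversible": "false"}
        )
        if r.reactants:
            lo = ET.SubElement(rx, f"{{{_SBML_NS}}}listOfReactants")
            for name, n in r.reactants.items():
                ET.SubElement(
                    lo,
                    f"{{{_SBML_NS}}}speciesReference",
                    {"species": name, "stoichiometry": str(n), "constant": "true"},
                )
        if r.products:
            lo = ET.SubElement(rx, f"{{{_SBML_NS}}}listOfProducts")
            for name, n in r.products.items():
                ET.SubElement(
                    lo,
                    f"{{{_SBML_NS}}}speciesReference",
                    {"species": name, "stoichiometry": str(n), "constant": "true"},
                )
        if r.modifiers:
            lo = ET.SubElement(rx, f"{{{_SBML_NS}}}listOfModifiers")
            for name in r.modifiers:
                ET.SubElement(
                    lo, f"{{{_SBML_NS}}}modifierSpeciesReference", {"species": name}
                )
        kl = ET.SubElement(rx, f"{{{_SBML_NS}}}kineticLaw")
        math = ET.SubElement(kl, f"{{{_MATHML_NS}}}math")
        _kinetic_mathml(math, r, network)

    text = ET.tostring(sbml, encoding="unicode", xml_declaration=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def _kinetic_mathml(math_el, reaction: Reaction, network: ReactionNetwork) -> None:
    """Emit the deterministic rate expression as MathML (mass action / Hill)."""
    from xml.etree import ElementTree as ET

    def ci(parent, name):
        el = ET.SubElement(parent, f"{{{_MATHML_NS}}}ci")
        el.text = f" {name} "

    def cn(parent, value):
        el = ET.SubElement(parent, f"{{{_MATHML_NS}}}cn")
        el.text = f" {value} "

    apply_el = ET.SubElement(math_el, f"{{{_MATHML_NS}}}apply")
    ET.SubElement(apply_el, f"{{{_MATHML_NS}}}times")
    ci(apply_el, reaction.rate_law.constant)
    if reaction.input_scale == "ros":
        ci(apply_el, "ros_input")
    elif reaction.input_scale == "scaffold":
        ci(apply_el, "scaffold_pool")
    if reaction.rate_law.kind == "hill_switch":
        law = reaction.rate_law
        ci(apply_el, law.hill_species)
        frac = ET.SubElement(apply_el, f"{{{_MATHML_NS}}}apply")
        ET.SubElement(frac, f"{{{_MATHML_NS}}}divide")
        num = ET.SubElement(frac, f"{{{_MATHML_NS}}}apply")
        ET.SubElement(num, f"{{{_MATHML_NS}}}power")
        ci(num, law.hill_species)
        ci(num, law.hill_n)
        den = ET.SubElement(frac, f"{{{_MATHML_NS}}}apply")
        ET.SubElement(den, f"{{{_MATHML_NS}}}plus")
        kpow = ET.SubElement(den, f"{{{_MATHML_NS}}}apply")
        ET.SubElement(kpow, f"{{{_MATHML_NS}}}power")
        ci(kpow, law.hill_K)
        ci(kpow, law.hill_n)
        xpow = ET.SubElement(den, f"{{{_MATHML_NS}}}apply")
        ET.SubElement(xpow, f"{{{_MATHML_NS}}}power")
        ci(xpow, law.hill_species)
        ci(xpow, law.hill_n)
        return
    for name, order in {**reaction.reactants, **reaction.modifiers}.items():
        if order == 1:
            ci(apply_el, name)
        else:
            p = ET.SubElement(apply_el, f"{{{_MATHML_NS}}}apply")
            ET.SubElement(p, f"{{{_MATHML_NS}}}power")
            ci(p, name)
            cn(p, order)
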