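"""Shared fixtures. Heavy simulation products are session-scoped so the
stochastic/deterministic cross-checks and the acceptance tests reuse them."""

from __future__ import annotations

import numpy as np
import pytest

from wntredox.network import (
    Compartment,
    ParameterSet,
    RateLaw,
    Reaction,
    ReactionNetwork,
    Species,
    build_network,
)
from wntredox.scenarios import make_scenario, run_virtual_experiment
from wntredox.simulate import ensemble_summary, ode_run, ssa_ensemble


def make_custom_network(species, reactions, values, volume_fraction=1.0):
    """Small helper to assemble ad-hoc test networks in one compartment."""
    comp = Compartment("cytosol", volume_fraction)
    return ReactionNetwork(
        species=[Species(n, "cytosol", x0) for n, x0 in species],
        reactions=reactions,
        compartments={"cytosol": comp},
        parameters=ParameterSet(dict(values), scaffold_pool=0.0, ros_baseline=1.0),
    )


def mass_action(label, reactants, products, constant, modifiers=None):
    return Reaction(
        label=label, group=label,
        reactants=dict(reactants), products=dict(products),
        modifiers=dict(modifiers or {}),
        rate_law=RateLaw("mass_action", constant),
    )


@pytest.fixture(scope="session")
def default_network():
    return build_network()


@pytest.fixture(scope="session")
def birth_network():
    """Pure birth process ∅→A at 5 molecules per hour."""
    return make_custom_network(
        [("A", 0)], [mass_action("birth", {}, {"A": 1}, "c")], {"c": 5.0}
    )


@pytest.fixture(scope="session")
def birth_death_network():
    """∅→A at 10/h, A→∅ at 1/h: steady state 10, A(t) = 10·(1−e⁻ᵗ)."""
    return make_custom_network(
        [("A", 0)],
        [
            mass_action("birth", {}, {"A": 1}, "c"),
            mass_action("death", {"A": 1}, {}, "k"),
        ],
        {"c": 10.0, "k": 1.0},
    )


@pytest.fixture(scope="session")
def ssa_ode_bundle(default_network):
    """200-run SSA ensemble of the default (Ref) network next to its ODE mean."""
    grid = np.array([0.0, 1.0, 6.0, 24.0])
    runs = ssa_ensemble(default_network, 24.0, 200, seed=42, grid=grid)
    summ = ensemble_summary(runs)
    traj = ode_run(default_network, 24.0, grid=grid)
    return {"grid": grid, "runs": runs, "summary": summ, "ode": traj}


@pytest.fixture(scope="session")
def ref_p5_ode(default_network):
    """Deterministic Ref-vs-P5 virtual experiment with calibrated defaults."""
    return run_virtual_experiment(
        default_network, make_scenario("ref"), make_scenario("p5"), engine="ode"
    )


@pytest.fixture(scope="session")
def recovery_sigma01(default_network):
    """Recovery of the three synthesis multipliers at lognormal σ = 0.1, n = 20."""
    from wntredox.calibration import recover

    truth = {"fold_ICAT": 1.65, "fold_SOX17": 1.58, "fold_TCF": 1.55}
    return recover(
        default_network, truth, noise_sd=0.1, n_replicates=20, seed=5,
        bounds={k: (0.5, 4.0) for k in truth},
    )
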