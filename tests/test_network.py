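"""Structural, kinetic and serialization tests of the reaction network."""

import math

import numpy as np
import pytest
from scipy.linalg import null_space

from wntredox.errors import ConfigurationError, InvariantViolation, ScopeError
from wntredox.network import (
    DVL_AGG_MONOMERS,
    Reaction,
    apply_scenario_scaling,
    build_network,
    check_network,
    default_parameters,
    network_from_yaml,
    network_to_dict,
    network_to_sbml,
    network_to_yaml,
    propensity,
)
from wntredox.simulate import ssa_run

from conftest import make_custom_network, mass_action


class TestStructure:
    def test_default_network_shape(self, default_network):
        assert len(default_network.compartments) == 2
        assert len(default_network.reaction_groups) == 18
        names = default_network.species_names
        assert len(names) == len(set(names))
        assert check_network(default_network) == []

    def test_feedback_flag_removes_exactly_one_reaction(self, default_network):
        off = build_network(options={"feedback": False})
        on_labels = {r.label for r in default_network.reactions}
        off_labels = {r.label for r in off.reactions}
        assert on_labels - off_labels == {"R11c"}
        # everything else identical (R11a/R11b keep the group alive)
        assert default_network.parameters.values == off.parameters.values
        assert len(off.reactions) == len(default_network.reactions) - 1

    @pytest.mark.parametrize("flag", ["icat_export", "sox17_codegradation"])
    def test_other_flags_remove_their_reaction(self, flag):
        off = build_network(options={flag: False})
        removed = {"icat_export": "R14", "sox17_codegradation": "R16"}[flag]
        assert removed not in {r.label for r in off.reactions}

    def test_unknown_flag_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown feature flag"):
            build_network(options={"turbo": True})

    def test_missing_parameter_is_named(self):
        params = default_parameters()
        del params.values["k_sox_deg"]
        with pytest.raises(ConfigurationError, match="k_sox_deg"):
            build_network(params)


class TestPropensity:
    def test_zero_when_reactant_absent(self, default_network):
        state = {name: 5 for name in default_network.species_names}
        state["TCFBC"] = 0
        r16 = next(r for r in default_network.reactions if r.label == "R16")
        assert propensity(state, r16, default_network) == 0.0

    def test_bimolecular_hand_value(self):
        net = make_custom_network(
            [("A", 10), ("B", 5), ("C", 0)],
            [mass_action("bind", {"A": 1, "B": 1}, {"C": 1}, "c")],
            {"c": 0.01},
            volume_fraction=1.0,
        )
        a = propensity({"A": 10, "B": 5, "C": 0}, net.reactions[0], net)
        assert a == pytest.approx(0.5, rel=1e-12)

    def test_hill_half_saturation(self, default_network):
        r8a = next(r for r in default_network.reactions if r.label == "R8a")
        K = default_network.parameters.get("dvl_agg_K")
        c = default_network.parameters.get("k_dvl_agg")
        state = {name: 0 for name in default_network.species_names}
        state["DVL_free"] = int(K)
        assert propensity(state, r8a, default_network) == pytest.approx(c * K / 2)

    def test_negative_copies_rejected(self, default_network):
        state = {name: 0 for name in default_network.species_names}
        state["BC_c"] = -1
        with pytest.raises(InvariantViolation):
            propensity(state, default_network.reactions[0], default_network)

    def test_matches_bruteforce_combinatorial_count(self, default_network):
        """Oracle equivalence on random small states (≤ 20 copies/species).

        The oracle recomputes every mass-action propensity from first
        principles: stochastic rate constant (with independent input/volume
        scaling) times the number of distinct reactant/modifier combinations.
        """
        rng = np.random.default_rng(2024)
        params = default_network.parameters
        comp_of = {s.name: s.compartment for s in default_network.species}
        for _ in range(100):
            state = {
                name: int(rng.integers(0, 21))
                for name in default_network.species_names
            }
            for rxn in default_network.reactions:
                expected = params.get(rxn.rate_law.constant)
                if rxn.input_scale == "ros":
                    expected *= default_network.ros_input
                elif rxn.input_scale == "scaffold":
                    expected *= params.scaffold_pool
                if rxn.rate_law.kind == "hill_switch":
                    x = state[rxn.rate_law.hill_species]
                    K = params.get(rxn.rate_law.hill_K)
                    n = params.get(rxn.rate_law.hill_n)
                    expected *= x * x**n / (K**n + x**n)
                    if any(state[s] < c for s, c in rxn.reactants.items()):
                        expected = 0.0
                else:
                    factors = {**rxn.reactants, **rxn.modifiers}
                    if sum(factors.values()) == 2:
                        expected /= default_network.compartments[
                            comp_of[next(iter(factors))]
                        ].volume_fraction
                    for name, count in factors.items():
                        # number of ordered ways to pick `count` molecules
                        expected *= math.perm(state[name], count)
                    if any(state[s] < c for s, c in rxn.reactants.items()):
                        expected = 0.0
                assert propensity(state, rxn, default_network) == pytest.approx(
                    expected, rel=1e-12, abs=1e-12
                )


class TestScenarioScaling:
    def test_scales_only_the_synthesis_constant(self, default_network):
        scaled = apply_scenario_scaling(default_network, {"ICAT": 1.65})
        before = default_network.parameters.values
        after = scaled.parameters.values
        assert after["k_icat_syn"] == pytest.approx(1.65 * before["k_icat_syn"])
        unchanged = {k: v for k, v in after.items() if k != "k_icat_syn"}
        assert unchanged == {k: v for k, v in before.items() if k != "k_icat_syn"}

    def test_identity_map_returns_equal_network(self, default_network):
        same = apply_scenario_scaling(default_network, {})
        assert same.parameters.values == default_network.parameters.values

    def test_membrane_gene_is_out_of_scope(self, default_network):
        with pytest.raises(ScopeError, match="outside the intracellular model scope"):
            apply_scenario_scaling(default_network, {"SOST": 1.57})

    def test_nonpositive_multiplier_rejected(self, default_network):
        with pytest.raises(ConfigurationError):
            apply_scenario_scaling(default_network, {"ICAT": 0.0})

    def test_unit_multipliers_preserve_trajectories_bitwise(self, default_network):
        scaled = apply_scenario_scaling(
            default_network, {"ICAT": 1.0, "SOX17": 1.0, "TCF": 1.0}
        )
        a = ssa_run(default_network, 2.0, seed=123)
        b = ssa_run(scaled, 2.0, seed=123)
        assert np.array_equal(a.values, b.values)
        assert a.n_events == b.n_events


class TestConservation:
    def test_declared_groups_lie_in_stoichiometry_null_space(self, default_network):
        """Independent oracle: each conserved weight vector must lie in the
        left null space of the non-exempt stoichiometry submatrix."""
        index = default_network.species_index()
        for group in default_network.conservation_groups:
            rows = [
                [r.products.get(s, 0) - r.reactants.get(s, 0) for s in index]
                for r in default_network.reactions
                if r.label not in group.exempt_labels
            ]
            S = np.array(rows, dtype=float)  # reactions × species
            w = np.zeros(len(index))
            for name, weight in group.weights.items():
                w[index[name]] = weight
            # w conserved <=> S·w = 0
            assert np.allclose(S @ w, 0.0), group.name
            # and w is representable in the null space basis of S
            basis = null_space(S)
            proj = basis @ (basis.T @ w)
            assert np.allclose(proj, w), group.name

    def test_dvl_monomer_weighting_uses_aggregate_size(self, default_network):
        group = next(
            g for g in default_network.conservation_groups if g.name == "DVL"
        )
        assert group.weights["DVL_agg"] == DVL_AGG_MONOMERS

    def test_perturbed_stoichiometry_reports_dvl_violation(self, default_network):
        broken = default_network.copy()
        idx = next(
            i for i, r in enumerate(broken.reactions) if r.label == "R8a"
        )
        r = broken.reactions[idx]
        broken.reactions[idx] = Reaction(
            label=r.label, group=r.group,
            reactants={"DVL_free": 1},  # loses one monomer per aggregate
            products=dict(r.products), modifiers=dict(r.modifiers),
            rate_law=r.rate_law,
        )
        violations = check_network(broken)
        assert any("DVL" in v for v in violations)

    def test_unknown_species_reference_reported(self, default_network):
        broken = default_network.copy()
        broken.reactions = list(broken.reactions) + [
            mass_action("bogus", {"XYZ": 1}, {}, "k_bc_syn")
        ]
        violations = check_network(broken)
        assert any("XYZ" in v for v in violations)


class TestSerialization:
    def test_yaml_round_trip_is_lossless(self, default_network, tmp_path):
        path = tmp_path / "model.yaml"
        network_to_yaml(default_network, path)
        loaded = network_from_yaml(path)
        assert network_to_dict(loaded) == network_to_dict(default_network)
        # and the round-tripped model simulates identically
        a = ssa_run(default_network, 1.0, seed=9)
        b = ssa_run(loaded, 1.0, seed=9)
        assert np.array_equal(a.values, b.values)

    def test_sbml_export_is_wellformed_and_complete(self, default_network, tmp_path):
        from xml.etree import ElementTree as ET

        path = tmp_path / "model.sbml.xml"
        network_to_sbml(default_network, path)
        root = ET.parse(path).getroot()
        ns = {"s": "http://www.sbml.org/sbml/level3/version1/core"}
        species = root.findall(".//s:species", ns)
        reactions = root.findall(".//s:reaction", ns)
        assert len(species) == len(default_network.species)
        assert len(reactions) == len(default_network.reactions)
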