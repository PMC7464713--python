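"""SSA and ODE engine tests: exactness, determinism, convergence, statistics."""

import numpy as np
import pytest
from scipy import stats

from wntredox.errors import SimulationError
from wntredox.simulate import (
    ensemble_summary,
    ode_run,
    save_ensemble_h5,
    ssa_ensemble,
    ssa_run,
    steady_state,
)

from conftest import make_custom_network, mass_action


class TestSSA:
    def test_pure_birth_counts_are_poisson(self, birth_network):
        """∅→A at 5/h over 24 h: event count ~ Poisson(120); the ensemble
        mean must sit within 3·√(120/n) of 120."""
        n = 300
        runs = ssa_ensemble(birth_network, 24.0, n, seed=10)
        counts = np.array([tr.values[-1, 0] for tr in runs])
        assert abs(counts.mean() - 120.0) < 3.0 * np.sqrt(120.0 / n)
        # exact chain: the event counter equals the birth count
        assert all(tr.n_events == tr.values[-1, 0] for tr in runs)

    def test_poisson_chi_square_goodness_of_fit(self, birth_network):
        """Counts over 4 h (λ = 20) from 1000 runs pass a χ² GoF at α = 0.01."""
        lam = 20.0
        runs = ssa_ensemble(birth_network, 4.0, 1000, seed=77)
        counts = np.array([tr.values[-1, 0] for tr in runs])
        cuts = np.array([12, 15, 17, 19, 21, 24, 27])  # bins: ≤12, 13-15, …, ≥28
        edges = np.concatenate([[-0.5], cuts + 0.5, [np.inf]])
        observed, _ = np.histogram(counts, bins=edges)
        cdf = stats.poisson.cdf(np.concatenate([cuts, [np.inf]]), lam)
        probs = np.diff(np.concatenate([[0.0], cdf]))
        _, p = stats.chisquare(observed, len(counts) * probs)
        assert p > 0.01

    def test_absorbing_state_flagged(self):
        net = make_custom_network(
            [("A", 7)], [mass_action("death", {"A": 1}, {}, "k")], {"k": 0.0}
        )
        tr = ssa_run(net, 10.0, seed=1)
        assert tr.absorbing
        assert np.all(tr.values == 7)
        assert tr.n_events == 0

    def test_seed_determinism(self, default_network):
        a = ssa_run(default_network, 3.0, seed=4242)
        b = ssa_run(default_network, 3.0, seed=4242)
        assert np.array_equal(a.values, b.values)
        assert a.n_events == b.n_events

    def test_different_seeds_differ(self, default_network):
        a = ssa_run(default_network, 3.0, seed=1)
        b = ssa_run(default_network, 3.0, seed=2)
        assert not np.array_equal(a.values, b.values)

    def test_no_negative_copies_ever(self, ssa_ode_bundle):
        for tr in ssa_ode_bundle["runs"]:
            assert tr.values.min() >= 0

    def test_invalid_t_end_rejected(self, default_network):
        with pytest.raises(ValueError):
            ssa_run(default_network, 0.0, seed=1)


class TestODE:
    def test_birth_death_closed_form(self, birth_death_network):
        grid = np.linspace(0.0, 24.0, 49)
        tr = ode_run(birth_death_network, 24.0, grid=grid)
        expected = 10.0 * (1.0 - np.exp(-grid))
        assert np.allclose(tr.values[:, 0], expected, rtol=1e-6, atol=1e-6)
        assert tr.values[-1, 0] == pytest.approx(10.0, rel=1e-6)

    def test_linear_shuttling_conserves_total(self):
        net = make_custom_network(
            [("A", 100), ("B", 0)],
            [
                mass_action("in", {"A": 1}, {"B": 1}, "kf"),
                mass_action("out", {"B": 1}, {"A": 1}, "kb"),
            ],
            {"kf": 0.8, "kb": 1.2},
        )
        tr = ode_run(net, 24.0)
        totals = tr.values.sum(axis=1)
        assert np.allclose(totals, 100.0, atol=1e-6)

    def test_full_network_tracks_ssa_ensemble_mean(self, ssa_ode_bundle):
        """Nuclear β-catenin from the mean-field ODE stays within 10% of the
        200-run SSA ensemble mean at 1, 6 and 24 h."""
        summ, ode = ssa_ode_bundle["summary"], ssa_ode_bundle["ode"]
        nuclear = ["BC_n", "ICATBC_n", "TCFBC"]
        for t in (1.0, 6.0, 24.0):
            i = list(ssa_ode_bundle["grid"]).index(t)
            ssa_val = sum(summ.mean[i][summ.species.index(s)] for s in nuclear)
            ode_val = sum(ode.values[i][ode.species.index(s)] for s in nuclear)
            assert ssa_val == pytest.approx(ode_val, rel=0.10)
            # and the bare nuclear pool too
            s_bc = summ.mean[i][summ.species.index("BC_n")]
            o_bc = ode.values[i][ode.species.index("BC_n")]
            assert s_bc == pytest.approx(o_bc, rel=0.10)

    def test_system_size_convergence_to_mean_field(self):
        """For the linear birth-death model scaled ×1/×10/×100 the relative
        gap between the SSA ensemble mean and the ODE solution shrinks
        monotonically (system-size expansion)."""
        gaps = []
        grid = np.linspace(0.0, 8.0, 9)
        for scale in (1, 10, 100):
            net = make_custom_network(
                [("A", 0)],
                [
                    mass_action("birth", {}, {"A": 1}, "c"),
                    mass_action("death", {"A": 1}, {}, "k"),
                ],
                {"c": 10.0 * scale, "k": 1.0},
            )
            runs = ssa_ensemble(net, 8.0, 400, seed=31, grid=grid)
            mean = np.mean([tr.values[:, 0] for tr in runs], axis=0)
            ode_vals = ode_run(net, 8.0, grid=grid).values[:, 0]
            # RMS relative gap over the interior grid (averages out the
            # Monte-Carlo noise of any single time point)
            rel = mean[1:] / ode_vals[1:] - 1.0
            gaps.append(float(np.sqrt(np.mean(rel**2))))
        assert gaps[0] > gaps[1] > gaps[2]


class TestEnsembleSummary:
    def test_identical_runs_have_zero_variance(self, default_network):
        a = ssa_run(default_network, 1.0, seed=5)
        b = ssa_run(default_network, 1.0, seed=5)
        summ = ensemble_summary([a, b])
        assert np.all(summ.variance == 0.0)
        assert np.all(summ.halfwidth == 0.0)

    def test_single_run_rejected(self, default_network):
        with pytest.raises(ValueError):
            ensemble_summary([ssa_run(default_network, 1.0, seed=5)])

    def test_mismatched_grids_rejected(self, birth_network):
        a = ssa_run(birth_network, 2.0, seed=1, grid=np.array([0.0, 1.0, 2.0]))
        b = ssa_run(birth_network, 2.0, seed=2, grid=np.array([0.0, 2.0]))
        with pytest.raises(ValueError):
            ensemble_summary([a, b])

    def test_halfwidth_covers_analytic_poisson_mean(self, birth_network):
        """With n = 500 runs the 95% CI of the mean contains the analytic
        Poisson mean 5t at ≥ 95% of interior grid points (seeded draw)."""
        grid = np.linspace(0.0, 24.0, 25)
        runs = ssa_ensemble(birth_network, 24.0, 500, seed=909, grid=grid)
        summ = ensemble_summary(runs)
        analytic = 5.0 * grid[1:]
        covered = np.abs(summ.mean[1:, 0] - analytic) <= summ.halfwidth[1:, 0]
        assert covered.mean() >= 0.95

    def test_halfwidth_shrinks_with_ensemble_size(self, birth_network):
        grid = np.array([0.0, 24.0])
        runs = ssa_ensemble(birth_network, 24.0, 400, seed=11, grid=grid)
        small = ensemble_summary(runs[:100])
        large = ensemble_summary(runs)
        assert large.halfwidth[-1, 0] < small.halfwidth[-1, 0]


class TestSteadyState:
    def test_birth_death_level(self, birth_death_network):
        ss = steady_state(birth_death_network, mode="ode")
        assert ss["A"] == pytest.approx(10.0, rel=1e-8)

    def test_ssa_ensemble_mode_matches_ode(self, default_network):
        """Long-run SSA time averages agree with the ODE fixed point within
        10% for every species above ~5 copies (sub-copy species are dominated
        by fluctuation effects the mean-field limit cannot represent)."""
        ode_ss = steady_state(default_network, mode="ode")
        ssa_ss = steady_state(default_network, mode="ssa-ensemble", n_runs=50, seed=3)
        for name, level in ode_ss.items():
            if level >= 5.0:
                assert ssa_ss[name] == pytest.approx(level, rel=0.10), name

    def test_nonconvergent_system_raises(self):
        # pure birth never reaches a steady state
        net = make_custom_network(
            [("A", 0)], [mass_action("birth", {}, {"A": 1}, "c")], {"c": 5.0}
        )
        with pytest.raises(SimulationError):
            steady_state(net, mode="ode", horizon=1.0, max_factor=2.0)

    def test_unknown_mode_rejected(self, birth_death_network):
        with pytest.raises(ValueError):
            steady_state(birth_death_network, mode="tau-leap")


def test_ensemble_h5_container_round_trips(tmp_path, birth_network):
    import h5py

    runs = ssa_ensemble(birth_network, 2.0, 5, seed=2, grid=np.array([0.0, 1.0, 2.0]))
    path = tmp_path / "ens.h5"
    save_ensemble_h5(path, runs)
    with h5py.File(path) as fh:
        assert fh["values"].shape == (5, 3, 1)
        assert list(fh["time"][...]) == [0.0, 1.0, 2.0]
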