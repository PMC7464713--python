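"""Virtual experiments: reference surface (Ref) vs sharp-edged micro-pillars (P5).

A scenario is a named condition: a dimensionless ROS input level plus per-gene
synthesis-rate fold multipliers (the measured mRNA fold changes of the
intracellular, differentially expressed components) and optional parameter /
initial-state patches. The P5 preset carries the microarray fold changes —
ICAT (CTNNBIP1) 1.65, SOX17 1.58, TCF4 1.55 — and a calibrated ROS input;
protein-level fold changes are emergent model output, never imposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .network import ReactionNetwork, apply_scenario_scaling
from .simulate import ensemble_summary, ode_run, ssa_ensemble, steady_state

__all__ = [
    "Scenario",
    "ExperimentReadout",
    "P5_FOLD_MAP",
    "P5_ROS_LEVEL",
    "READOUTS",
    "make_scenario",
    "apply_scenario",
    "run_virtual_experiment",
    "scan_inhibitors",
]

#: mRNA fold changes applied as synthesis-rate multipliers under P5.
P5_FOLD_MAP: dict[str, float] = {"ICAT": 1.65, "SOX17": 1.58, "TCF": 1.55}

#: Calibrated dimensionless ROS input of the P5 condition (Ref is 1.0).
#: Obtained by the calibration module; see docs/methods.md.
P5_ROS_LEVEL: float = 7.7


@dataclass
class Scenario:
    label: str
    ros_level: float
    fold_map: dict[str, float] = field(default_factory=dict)
    parameter_overrides: dict[str, float] = field(default_factory=dict)
    initial_overrides: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ros_level < 0:
            raise ConfigurationError(f"ros_level must be >= 0, got {self.ros_level}")
        for gene, m in self.fold_map.items():
            if not m > 0:
                raise ConfigurationError(
                    f"fold multiplier for {gene!r} must be > 0, got {m}"
                )


def make_scenario(
    label: str,
    ros_level: float | None = None,
    fold_map: Mapping[str, float] | None = None,
    overrides: Mapping | None = None,
) -> Scenario:
    """Build a scenario; ``label`` "ref" and "p5" are presets.

    Ref: baseline ROS, identity multipliers. P5: calibrated ROS level plus the
    measured fold map. Explicit arguments override the preset values.
    """
    key = label.lower()
    if key == "ref":
        preset_ros, preset_folds = 1.0, {}
        label = "Ref"
    elif key == "p5":
        preset_ros, preset_folds = P5_ROS_LEVEL, dict(P5_FOLD_MAP)
        label = "P5"
    else:
        preset_ros, preset_folds = 1.0, {}
    overrides = dict(overrides or {})
    return Scenario(
        label=label,
        ros_level=preset_ros if ros_level is None else float(ros_level),
        fold_map=dict(preset_folds if fold_map is None else fold_map),
        parameter_overrides=dict(overrides.get("parameters", {})),
        initial_overrides=dict(overrides.get("initial_copies", {})),
    )


def apply_scenario(network: ReactionNetwork, scenario: Scenario) -> ReactionNetwork:
    """Instantiate a scenario on a network template (template is untouched)."""
    net = network.with_ros(scenario.ros_level * network.parameters.ros_baseline)
    if scenario.fold_map:
        net = apply_scenario_scaling(net, scenario.fold_map)
    for name, value in scenario.parameter_overrides.items():
        if name not in net.parameters.values:
            raise ConfigurationError(f"unknown parameter override {name!r}")
        net.parameters.values[name] = float(value)
    if scenario.initial_overrides:
        net = net.with_initial_copies(scenario.initial_overrides)
    return net


# ---------------------------------------------------------------------------
# Readouts
# ---------------------------------------------------------------------------

def _target_rate(copies: Mapping[str, float], network: ReactionNetwork) -> float:
    # target-gene expression rate = k_tx × TCF/β-catenin complex
    return network.parameters.get("k_tx") * copies["TCFBC"]


#: Named readouts evaluated on a copy-number state.
READOUTS: dict[str, Callable[[Mapping[str, float], ReactionNetwork], float]] = {
    "nuclear_bc": lambda c, n: c["BC_n"] + c["ICATBC_n"] + c["TCFBC"],
    "cytosolic_bc": lambda c, n: c["BC_c"] + c["ICATBC_c"],
    "total_bc": lambda c, n: c["BC_c"] + c["ICATBC_c"] + c["BC_n"] + c["ICATBC_n"] + c["TCFBC"],
    "tcfbc": lambda c, n: c["TCFBC"],
    "tcf_free": lambda c, n: c["TCF"],
    "tcf_total": lambda c, n: c["TCF"] + c["TCFBC"],
    "icat_total": lambda c, n: c["ICAT_c"] + c["ICAT_n"] + c["ICATBC_c"] + c["ICATBC_n"],
    "sox_total": lambda c, n: c["SOX17"],
    "target_rate": _target_rate,
    "target_protein": lambda c, n: c["TargetProtein"],
}


def evaluate_readout(
    name: str, copies: Mapping[str, float], network: ReactionNetwork
) -> float:
    fn = READOUTS.get(name)
    if fn is not None:
        return float(fn(copies, network))
    if name in copies:  # bare species name
        return float(copies[name])
    raise ConfigurationError(
        f"unknown readout {name!r}; known: {sorted(READOUTS)} or a species name"
    )


@dataclass
class ExperimentReadout:
    """Paired-scenario readout (b relative to a) at the probed times."""

    label_a: str
    label_b: str
    times: tuple[float, ...]
    nuclear_level_a: dict[float, float]
    nuclear_level_b: dict[float, float]
    nuclear_fold: dict[float, float]
    cytosolic_fold: dict[float, float]
    tcfbc_level: dict[float, float]
    target_rate_a: dict[float, float]
    target_rate_b: dict[float, float]
    target_expression_ratio: dict[float, float]
    tcf_free: dict[float, float]
    engine: str
    n_runs: int | None = None

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.times:
            rows.append(
                {
                    "time_h": t,
                    "nuclear_bc_a": self.nuclear_level_a[t],
                    "nuclear_bc_b": self.nuclear_level_b[t],
                    "nuclear_bc_fold": self.nuclear_fold[t],
                    "cytosolic_bc_fold": self.cytosolic_fold[t],
                    "tcfbc": self.tcfbc_level[t],
                    "target_rate_a": self.target_rate_a[t],
                    "target_rate_b": self.target_rate_b[t],
                    "target_expression_ratio": self.target_expression_ratio[t],
                    "tcf_free": self.tcf_free[t],
                }
            )
        return pd.DataFrame(rows)


def _mean_states(
    network: ReactionNetwork,
    t_end: float,
    times: Sequence[float],
    engine: str,
    n_runs: int,
    seed: int,
) -> dict[float, dict[str, float]]:
    grid = np.unique(np.concatenate([[0.0], np.asarray(times, dtype=float)]))
    if engine == "ode":
        traj = ode_run(network, t_end, grid=grid)
        return {t: traj.at(t) for t in times}
    if engine == "ssa":
        runs = ssa_ensemble(network, t_end, n_runs, seed, grid=grid)
        summ = ensemble_summary(runs)
        out = {}
        for t in times:
            idx = int(np.argmin(np.abs(summ.times - t)))
            out[t] = dict(zip(summ.species, summ.mean[idx]))
        return out
    raise ValueError(f"unknown engine {engine!r}")


def run_virtual_experiment(
    network: ReactionNetwork,
    scenario_a: Scenario,
    scenario_b: Scenario,
    engine: str = "ode",
    n_runs: int = 200,
    seed: int = 7,
    times: Sequence[float] = (1.0, 24.0),
) -> ExperimentReadout:
    """Simulate two scenarios from the same template and compare them.

    Stochastic comparisons use matched seeds (common random numbers), so an
    identical pair of scenarios yields fold 1 exactly.
    """
    times = tuple(float(t) for t in times)
    t_end = max(times)
    net_a = apply_scenario(network, scenario_a)
    net_b = apply_scenario(network, scenario_b)
    states_a = _mean_states(net_a, t_end, times, engine, n_runs, seed)
    states_b = _mean_states(net_b, t_end, times, engine, n_runs, seed)

    def read(name, states, net):
        return {t: evaluate_readout(name, states[t], net) for t in times}

    nuc_a = read("nuclear_bc", states_a, net_a)
    nuc_b = read("nuclear_bc", states_b, net_b)
    cyt_a = read("cytosolic_bc", states_a, net_a)
    cyt_b = read("cytosolic_bc", states_b, net_b)
    rate_a = read("target_rate", states_a, net_a)
    rate_b = read("target_rate", states_b, net_b)
    return ExperimentReadout(
        label_a=scenario_a.label,
        label_b=scenario_b.label,
        times=times,
        nuclear_level_a=nuc_a,
        nuclear_level_b=nuc_b,
        nuclear_fold={t: nuc_b[t] / nuc_a[t] for t in times},
        cytosolic_fold={t: cyt_b[t] / cyt_a[t] for t in times},
        tcfbc_level=read("tcfbc", states_b, net_b),
        target_rate_a=rate_a,
        target_rate_b=rate_b,
        target_expression_ratio={t: rate_b[t] / rate_a[t] for t in times},
        tcf_free=read("tcf_free", states_b, net_b),
        engine=engine,
        n_runs=n_runs if engine == "ssa" else None,
    )


# ---------------------------------------------------------------------------
# Parameter scans
# ---------------------------------------------------------------------------

_SCAN_AXES = ("ICAT", "SOX17", "TCF", "ROS")


def _monotonicity(values: np.ndarray, rtol: float = 1e-9) -> str:
    diffs = np.diff(values)
    scale = np.maximum(np.abs(values[:-1]), 1e-12)
    if np.all(diffs >= -rtol * scale):
        return "non-decreasing"
    if np.all(diffs <= rtol * scale):
        return "non-increasing"
    return "non-monotone"


def scan_inhibitors(
    network: ReactionNetwork,
    axis: str,
    grid: Sequence[float],
    readouts: Sequence[str] = ("tcfbc", "total_bc", "tcf_free", "target_rate"),
    engine: str = "ode",
    tol: float = 1e-9,
) -> pd.DataFrame:
    """Steady-state dose-response along one inhibitor (or the ROS input) axis.

    One row per grid multiplier; monotonicity diagnostics for each readout are
    attached in ``DataFrame.attrs["monotonicity"]``.
    """
    if axis not in _SCAN_AXES:
        raise ConfigurationError(f"unknown scan axis {axis!r}; choose from {_SCAN_AXES}")
    grid = list(grid)
    if not grid:
        raise ValueError("scan grid must be non-empty")
    arr = np.asarray(grid, dtype=float)
    if np.any(arr <= 0) or np.any(np.diff(arr) <= 0):
        raise ValueError("scan grid must be positive and strictly increasing")
    if engine != "ode":
        raise ConfigurationError("scan_inhibitors supports the ODE engine only")

    rows = []
    for m in arr:
        if axis == "ROS":
            net = network.with_ros(m * network.parameters.ros_baseline)
        else:
            net = apply_scenario_scaling(network, {axis: m})
        ss = steady_state(net, mode="ode", tol=tol)
        row = {"multiplier": m}
        for name in readouts:
            row[name] = evaluate_readout(name, ss, net)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["axis"] = axis
    df.attrs["monotonicity"] = {
        name: _monotonicity(df[name].to_numpy()) for name in readouts
    }
    return df
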