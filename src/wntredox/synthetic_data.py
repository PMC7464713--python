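"""Synthetic inputs for the pipeline: expression tables and noisy time courses.

No external data downloads are required anywhere in the package; these
generators produce (i) per-gene fold-change tables with a controlled fraction
of truly regulated genes, emulating the shape of a two-condition microarray
comparison (~21k genes, ~1.5% regulated, balanced up/down), and (ii) noisy
time-course observation tables of model readouts, mimicking the structure of
flow-cytometry measurements at 1 h and 24 h. All generators are pure
functions of their spec, seed included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .calibration import Observation, ObservationTable
from .errors import ConfigurationError
from .deg_filter import GeneRecord
from .network import ReactionNetwork
from .scenarios import Scenario, apply_scenario, evaluate_readout
from .simulate import ode_run

__all__ = [
    "ExpressionTableSpec",
    "TimecourseSpec",
    "gen_expression_table",
    "gen_noisy_timecourse",
]


@dataclass(frozen=True)
class ExpressionTableSpec:
    """Generative model of a two-condition per-gene expression table.

    Regulated genes receive a signed log2 effect of magnitude
    ``effect_size_log2`` (sign ±1 with equal probability) plus per-gene
    Gaussian noise, and a p-value drawn from Beta(a, b) with sharply sub-0.05
    mass; null genes have log2 fold change ~ N(0, noise) and uniform p-values.
    """

    n_genes: int
    frac_regulated: float
    effect_size_log2: float = 1.0
    noise_sd_log2: float = 0.1
    null_p_uniform: bool = True
    p_beta: tuple[float, float] = (0.5, 20.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if not (0.0 <= self.frac_regulated <= 1.0):
            raise ConfigurationError("frac_regulated must be in [0, 1]")
        if self.noise_sd_log2 < 0 or self.effect_size_log2 < 0:
            raise ConfigurationError("effect size and noise sd must be >= 0")


def _signed_fold(log2fc: np.ndarray) -> np.ndarray:
    ratio = np.exp2(log2fc)
    return np.where(ratio >= 1.0, ratio, -1.0 / ratio)


def gen_expression_table(spec: ExpressionTableSpec) -> list[GeneRecord]:
    """Draw a synthetic per-gene table; deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    regulated = rng.random(spec.n_genes) < spec.frac_regulated
    sign = rng.choice((-1.0, 1.0), size=spec.n_genes)
    noise = (
        rng.normal(0.0, spec.noise_sd_log2, size=spec.n_genes)
        if spec.noise_sd_log2 > 0
        else np.zeros(spec.n_genes)
    )
    log2fc = np.where(regulated, sign * spec.effect_size_log2 + noise, noise)
    a, b = spec.p_beta
    p_reg = rng.beta(a, b, size=spec.n_genes)
    p_null = rng.random(spec.n_genes) if spec.null_p_uniform else p_reg
    p = np.where(regulated, p_reg, p_null)
    # p-values live in (0, 1]; guard the measure-zero draw p == 0
    p = np.maximum(p, np.finfo(float).tiny)
    fold = _signed_fold(log2fc)
    return [
        GeneRecord(
            symbol=f"G{i:05d}",
            fold_change=float(fold[i]),
            p_value=float(p[i]),
            pathway_tags=frozenset({"regulated"} if regulated[i] else ()),
        )
        for i in range(spec.n_genes)
    ]


@dataclass(frozen=True)
class TimecourseSpec:
    """Noisy readout table for a scenario pair at the probed times."""

    scenarios: tuple[Scenario, Scenario]
    times: tuple[float, ...] = (1.0, 24.0)
    readouts: tuple[str, ...] = ("total_bc", "nuclear_bc")
    noise_sd: float = 0.1
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if any(t <= 0 for t in self.times):
            raise ConfigurationError("observation times must be > 0")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")


def gen_noisy_timecourse(
    network: ReactionNetwork, spec: TimecourseSpec
) -> ObservationTable:
    """Deterministic model readouts × lognormal multiplicative noise.

    The deterministic (mean-field) model is run once per scenario; each
    replicate multiplies every readout by an independent LogNormal(0, σ)
    factor. σ = 0 reproduces the noiseless readouts exactly.
    """
    rng = np.random.default_rng(spec.seed)
    grid = np.unique(np.concatenate([[0.0], np.asarray(spec.times, dtype=float)]))
    t_end = float(max(spec.times))
    rows: list[Observation] = []
    for scenario in spec.scenarios:
        net = apply_scenario(network, scenario)
        traj = ode_run(net, t_end, grid=grid)
        for _ in range(spec.n_replicates):
            for t in spec.times:
                state = traj.at(t)
                for name in spec.readouts:
                    value = evaluate_readout(name, state, net)
                    if spec.noise_sd > 0:
                        value *= float(np.exp(rng.normal(0.0, spec.noise_sd)))
                    rows.append(Observation(name, float(t), scenario.label, value))
    return ObservationTable(rows)
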