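"""Exact stochastic (SSA) and mean-field (ODE) execution of the network.

The stochastic engine is Gillespie's direct method — an exact sampler of the
continuous-time Markov chain defined by the reaction network. The ODE engine
integrates the mean-field limit dx/dt = Sᵀ·v(x) and serves as the
deterministic counterpart for calibration, parameter scans and cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.integrate import solve_ivp
from scipy.optimize import root

from ._compile import CompiledNetwork, compile_network, rhs
from .errors import SimulationError
from .network import ReactionNetwork

__all__ = [
    "SystemState",
    "Trajectory",
    "EnsembleSummary",
    "ssa_run",
    "ssa_ensemble",
    "ode_run",
    "ensemble_summary",
    "steady_state",
    "save_ensemble_h5",
]

_SEED_MOD = 2**31


@dataclass
class SystemState:
    """Copy-number state of the CTMC at one time point."""

    time: float
    copies: dict[str, int]

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("time must be >= 0")
        for name, n in self.copies.items():
            if n < 0:
                raise ValueError(f"negative copy number: {name} = {n}")


@dataclass
class Trajectory:
    """Time-stamped state sequence sampled on a fixed grid.

    SSA trajectories hold integer copies (last-event hold, right-continuous);
    ODE trajectories hold continuous copies.
    """

    times: np.ndarray
    species: list[str]
    values: np.ndarray  # (T, S)
    seed: int | None = None
    label: str = ""
    absorbing: bool = False
    n_events: int | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.species)
        df.insert(0, "time", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.species.index(name)]

    def at(self, t: float) -> dict[str, float]:
        """State at grid time ``t`` (must be a grid point)."""
        idx = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[idx] - t) > 1e-9 * max(1.0, abs(t)):
            raise KeyError(f"time {t} is not on the trajectory grid")
        return dict(zip(self.species, self.values[idx]))


@dataclass
class EnsembleSummary:
    """Pointwise ensemble statistics on a shared time grid."""

    times: np.ndarray
    species: list[str]
    mean: np.ndarray
    variance: np.ndarray
    halfwidth: np.ndarray  # normal-approximation 95% CI half width of the mean
    n_runs: int

    def mean_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.mean, columns=self.species)
        df.insert(0, "time", self.times)
        return df

    def mean_of(self, name: str) -> np.ndarray:
        return self.mean[:, self.species.index(name)]


# ---------------------------------------------------------------------------
# Gillespie direct method (numba-compiled inner loop)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _ssa_core(
    x0, t_end, grid, seed,
    c_eff, prop_ptr, prop_species, prop_order,
    react_ptr, react_species, react_need,
    kind, hill_idx, hill_K, hill_n, net,
):  # pragma: no cover - exercised through ssa_run
    np.random.seed(seed)
    S = x0.shape[0]
    R = c_eff.shape[0]
    G = grid.shape[0]
    x = x0.copy()
    out = np.zeros((G, S), dtype=np.int64)
    a = np.zeros(R)
    gi = 0
    t = 0.0
    n_events = 0
    absorbing = False
    while True:
        a0 = 0.0
        for r in range(R):
            ar = c_eff[r]
            ok = True
            for j in range(react_ptr[r], react_ptr[r + 1]):
                if x[react_species[j]] < react_need[j]:
                    ok = False
                    break
            if not ok:
                ar = 0.0
            elif kind[r] == 1:
                xi = float(x[hill_idx[r]])
                ar = ar * xi * xi ** hill_n[r] / (hill_K[r] ** hill_n[r] + xi ** hill_n[r])
            else:
                for j in range(prop_ptr[r], prop_ptr[r + 1]):
                    xs = x[prop_species[j]]
                    if prop_order[j] == 1:
                        ar *= xs
                    else:
                        ar *= xs * (xs - 1)
            a[r] = ar
            a0 += ar
        if a0 <= 0.0:
            absorbing = True
            break
        t_next = t + np.random.exponential(1.0 / a0)
        while gi < G and grid[gi] < t_next:
            for s in range(S):
                out[gi, s] = x[s]
            gi += 1
        if t_next > t_end:
            break
        u = np.random.random() * a0
        acc = 0.0
        rsel = R - 1
        for r in range(R):
            acc += a[r]
            if u < acc:
                rsel = r
                break
        for s in range(S):
            x[s] += net[rsel, s]
            if x[s] < 0:
                # unreachable if propensities zero correctly; guards the CTMC
                raise ValueError("negative copy number after reaction firing")
        t = t_next
        n_events += 1
    while gi < G:
        for s in range(S):
            out[gi, s] = x[s]
        gi += 1
    return out, n_events, absorbing


def _default_grid(t_end: float) -> np.ndarray:
    return np.linspace(0.0, t_end, int(round(t_end * 10)) + 1)


def ssa_run(
    network: ReactionNetwork,
    t_end: float,
    seed: int,
    grid: np.ndarray | None = None,
    label: str = "",
    compiled: CompiledNetwork | None = None,
) -> Trajectory:
    """One exact Gillespie direct-method realization, sampled on ``grid``.

    Identical ``network``/``t_end``/``seed`` give bit-identical trajectories.
    If the chain absorbs (total propensity 0) before ``t_end`` the state is
    legally held constant and the trajectory is flagged ``absorbing``.
    """
    if not t_end > 0:
        raise ValueError("t_end must be > 0")
    comp = compiled if compiled is not None else compile_network(network)
    grid = _default_grid(t_end) if grid is None else np.asarray(grid, dtype=float)
    if grid.size and (grid[0] < 0 or grid[-1] > t_end + 1e-12 or np.any(np.diff(grid) <= 0)):
        raise ValueError("grid must be strictly increasing within [0, t_end]")
    out, n_events, absorbing = _ssa_core(
        comp.x0, float(t_end), grid, int(seed) % _SEED_MOD,
        comp.c_eff, comp.prop_ptr, comp.prop_species, comp.prop_order,
        comp.react_ptr, comp.react_species, comp.react_need,
        comp.kind, comp.hill_idx, comp.hill_K, comp.hill_n, comp.net,
    )
    return Trajectory(
        times=grid, species=list(comp.species), values=out,
        seed=int(seed), label=label, absorbing=bool(absorbing),
        n_events=int(n_events),
    )


def ssa_ensemble(
    network: ReactionNetwork,
    t_end: float,
    n_runs: int,
    seed: int,
    grid: np.ndarray | None = None,
    label: str = "",
) -> list[Trajectory]:
    """Ensemble of independent runs; run *i* uses seed ``seed + i`` (mod 2³¹)."""
    comp = compile_network(network)
    grid = _default_grid(t_end) if grid is None else np.asarray(grid, dtype=float)
    return [
        ssa_run(network, t_end, (seed + i) % _SEED_MOD, grid=grid, label=label, compiled=comp)
        for i in range(n_runs)
    ]


# ---------------------------------------------------------------------------
# Mean-field ODE
# ---------------------------------------------------------------------------

def ode_run(
    network: ReactionNetwork,
    t_end: float,
    rtol: float = 1e-8,
    atol: float = 1e-8,
    grid: np.ndarray | None = None,
    x0: np.ndarray | None = None,
    label: str = "",
    compiled: CompiledNetwork | None = None,
) -> Trajectory:
    """Integrate the mean-field ODE; dense output on the requested grid."""
    comp = compiled if compiled is not None else compile_network(network)
    grid = _default_grid(t_end) if grid is None else np.asarray(grid, dtype=float)
    start = comp.x0.astype(float) if x0 is None else np.asarray(x0, dtype=float)
    sol = solve_ivp(
        lambda t, x: rhs(comp, x),
        (0.0, float(t_end)),
        start,
        method="LSODA",
        t_eval=grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SimulationError(f"ODE integration failed: {sol.message}")
    return Trajectory(
        times=grid, species=list(comp.species), values=sol.y.T.copy(),
        seed=None, label=label,
    )


def ensemble_summary(runs: list[Trajectory]) -> EnsembleSummary:
    """Pointwise mean/variance/95%-CI half-width over an ensemble."""
    if len(runs) < 2:
        raise ValueError("ensemble_summary needs at least 2 runs")
    ref = runs[0]
    for tr in runs[1:]:
        if tr.species != ref.species or not np.array_equal(tr.times, ref.times):
            raise ValueError("all runs must share one species order and time grid")
    stack = np.stack([tr.values for tr in runs]).astype(float)
    mean = stack.mean(axis=0)
    var = stack.var(axis=0, ddof=1)
    half = 1.959963984540054 * np.sqrt(var / len(runs))
    return EnsembleSummary(
        times=ref.times, species=list(ref.species),
        mean=mean, variance=var, halfwidth=half, n_runs=len(runs),
    )


# ---------------------------------------------------------------------------
# Steady state
# ---------------------------------------------------------------------------

def steady_state(
    network: ReactionNetwork,
    mode: str = "ode",
    tol: float = 1e-8,
    horizon: float = 24.0,
    max_factor: float = 10.0,
    n_runs: int = 50,
    seed: int = 0,
) -> dict[str, float]:
    """Steady-state species levels.

    ODE mode integrates until the maximum relative time derivative drops below
    ``tol`` per hour (at most ``max_factor × horizon``), then polishes the
    fixed point with a Newton-type root solve. SSA mode returns the long-run
    time average over the second half of a ``max_factor × horizon`` window,
    averaged over ``n_runs`` runs.
    """
    comp = compile_network(network)
    if mode == "ode":
        x = comp.x0.astype(float)
        t_max = max_factor * horizon
        t_done = 0.0
        residual = np.inf
        while t_done < t_max:
            sol = solve_ivp(
                lambda t, y: rhs(comp, y), (0.0, horizon), x,
                method="LSODA", rtol=1e-10, atol=1e-10,
            )
            if not sol.success:
                raise SimulationError(f"ODE integration failed: {sol.message}")
            x = sol.y[:, -1]
            t_done += horizon
            dx = rhs(comp, x)
            residual = float(np.max(np.abs(dx) / np.maximum(np.abs(x), 1.0)))
            if residual < tol:
                break
        # Newton polish for solver-precision fixed points
        polished = root(lambda y: rhs(comp, y), x, method="hybr")
        if polished.success:
            y = polished.x
            close = np.linalg.norm(y - x) <= 0.1 * (np.linalg.norm(x) + 1.0)
            if close and np.all(y > -1e-6):
                x = np.maximum(y, 0.0)
                residual = float(np.max(np.abs(rhs(comp, x)) / np.maximum(np.abs(x), 1.0)))
        if residual >= tol:
            raise SimulationError(
                f"steady state not reached within t = {t_max} h "
                f"(max relative residual {residual:.3e}/h)"
            )
        return dict(zip(comp.species, x))

    if mode == "ssa-ensemble":
        t_end = max_factor * horizon
        grid = np.linspace(0.0, t_end, int(round(t_end * 2)) + 1)
        runs = ssa_ensemble(network, t_end, n_runs, seed, grid=grid)
        half = grid >= t_end / 2.0
        stack = np.stack([tr.values[half] for tr in runs]).astype(float)
        levels = stack.mean(axis=(0, 1))
        return dict(zip(comp.species, levels))

    raise ValueError(f"unknown steady-state mode {mode!r}")


# ---------------------------------------------------------------------------
# Ensemble container export
# ---------------------------------------------------------------------------

def save_ensemble_h5(path, runs: list[Trajectory]) -> None:
    """Write an ensemble as an HDF5 container (runs × grid × species)."""
    import h5py

    if not runs:
        raise ValueError("empty ensemble")
    ref = runs[0]
    with h5py.File(path, "w") as fh:
        fh.create_dataset("time", data=ref.times)
        fh.create_dataset("values", data=np.stack([tr.values for tr in runs]))
        fh.create_dataset(
            "species", data=np.array(ref.species, dtype=h5py.string_dtype())
        )
        fh.create_dataset("seeds", data=np.array([tr.seed or 0 for tr in runs]))
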