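"""Derived measures: response function, dynamic range, energy, classification.

The response function F(h) is the mean firing rate of a target compartment
(the soma by default) against the external input rate h.  Its dynamic
range is

    Delta = 10 * log10(h90 / h10)

where h10 and h90 are the input rates producing 10% and 90% of the maximum
firing rate of the sampled curve, located by linear interpolation of F
against log10(h) at the first upward crossing.

Energy measures, with S_i the spike tally of compartment i over a run
(S_0 = soma) and N dendritic compartments:

    E     = sum_{i=1..N} S_i / S_0          (dendritic spikes per somatic spike)
    E_rel = E / N

E_rel < 1 marks the energy-efficient regime (dendrites fire less, per
compartment, than the soma they drive).  Both are undefined when the soma
never fires; such cells are flagged and excluded from parameter-space
averages rather than reported as infinite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dynamics import DynamicsParams, SpikeCounts, firing_rate, simulate
from .morphology import Morphology

__all__ = [
    "ResponseCurve",
    "DynamicRangeResult",
    "EnergyResult",
    "UndefinedDynamicRange",
    "DynamicRangeOutOfGrid",
    "cell_seed",
    "response_curve",
    "dynamic_range",
    "energy",
    "energy_grid",
    "parameter_space_mean",
    "classify",
    "default_p_grid",
    "default_h_grid",
]


class UndefinedDynamicRange(ValueError):
    """The response curve never leaves zero."""


class DynamicRangeOutOfGrid(ValueError):
    """F10 or F90 is not bracketed from below by the sampled h-grid."""

    def __init__(self, bound: str, message: str):
        super().__init__(message)
        self.bound = bound


@dataclass(frozen=True)
class ResponseCurve:
    h_grid: np.ndarray
    F: np.ndarray
    target: int
    P: float
    n_steps: int
    seed: int


@dataclass(frozen=True)
class DynamicRangeResult:
    F_max: float
    F10: float
    F90: float
    h10: float
    h90: float
    delta: float


@dataclass(frozen=True)
class EnergyResult:
    E: float
    E_rel: float
    N: int
    defined: bool


def default_p_grid() -> np.ndarray:
    """P in {0.50, 0.55, ..., 1.00} (11 values)."""
    return np.round(np.linspace(0.5, 1.0, 11), 10)

def default_h_grid(points_per_decade: int = 10) -> np.ndarray:
    """h log-spaced over [1e-2, 1e3] Hz."""
    n = 5 * points_per_decade + 1
    return np.logspace(-2.0, 3.0, n)


def cell_seed(master_seed: int, *indices: int) -> int:
    """Stable per-cell seed derived from the master seed and cell indices."""
    ss = np.random.SeedSequence((int(master_seed),) + tuple(int(i) for i in indices))
    return int(ss.generate_state(1)[0] % (2**31))


def response_curve(
    m: Morphology,
    P: float,
    h_grid,
    *,
    n_steps: int,
    seed: int,
    dt: float = 0.001,
    refractory_steps: int = 7,
    drive_soma: bool = True,
    transient_steps: int = 0,
    target: int | None = None,
) -> ResponseCurve:
    """Simulate once per h value (independent derived seeds) and collect
    the target compartment's mean firing rate."""
    h_grid = np.asarray(h_grid, dtype=float)
    if h_grid.size == 0:
        raise ValueError("h_grid must be non-empty")
    if np.any(np.diff(h_grid) <= 0):
        raise ValueError("h_grid must be strictly increasing")
    if target is None:
        target = m.soma_id
    F = np.empty_like(h_grid)
    for j, h in enumerate(h_grid):
        params = DynamicsParams(
            P=P, h=float(h), dt=dt, refractory_steps=refractory_steps,
            n_steps=n_steps, seed=cell_seed(seed, j),
            drive_soma=drive_soma, transient_steps=transient_steps,
        )
        counts = simulate(m, params)
        F[j] = firing_rate(counts, target)
    return ResponseCurve(h_grid=h_grid, F=F, target=target, P=P,
                         n_steps=n_steps, seed=seed)


def _first_upward_crossing(logh: np.ndarray, F: np.ndarray,
                           level: float, bound: str) -> float:
    """log10(h) at the first crossing of ``level`` from below."""
    if F[0] >= level:
        raise DynamicRangeOutOfGrid(
            bound, f"{bound}: curve already at or above the level at the "
            f"smallest sampled h"
        )
    for j in range(1, len(F)):
        if F[j] >= level:
            lo, hi = F[j - 1], F[j]
            frac = (level - lo) / (hi - lo)
            return logh[j - 1] + frac * (logh[j] - logh[j - 1])
    raise DynamicRangeOutOfGrid(
        bound, f"{bound}: level never reached on the sampled grid"
    )


def dynamic_range(curve: ResponseCurve) -> DynamicRangeResult:
    """Dynamic range of a sampled response curve.

    F_max is the maximum of the sampled curve; h10/h90 are interpolated
    linearly in (log10 h, F) at the first crossing from below of
    0.1 F_max / 0.9 F_max.
    """
    F = np.asarray(curve.F, dtype=float)
    h = np.asarray(curve.h_grid, dtype=float)
    if F.size < 2:
        raise ValueError("need at least 2 points")
    F_max = float(F.max())
    if F_max <= 0:
        raise UndefinedDynamicRange("response curve is identically zero")
    F10, F90 = 0.1 * F_max, 0.9 * F_max
    logh = np.log10(h)
    l10 = _first_upward_crossing(logh, F, F10, "h10")
    l90 = _first_upward_crossing(logh, F, F90, "h90")
    delta = 10.0 * (l90 - l10)
    return DynamicRangeResult(
        F_max=F_max, F10=F10, F90=F90,
        h10=float(10.0 ** l10), h90=float(10.0 ** l90), delta=float(delta),
    )


def energy(counts: SpikeCounts) -> EnergyResult:
    """Total and relative energy consumption from one run's spike tallies."""
    S0 = counts.soma_count
    dend = counts.dendritic_counts
    N = int(dend.size)
    if S0 == 0 or N == 0:
        return EnergyResult(E=math.nan, E_rel=math.nan, N=N, defined=False)
    E = float(dend.sum()) / S0
    return EnergyResult(E=E, E_rel=E / N, N=N, defined=True)


def energy_grid(
    m: Morphology,
    p_grid,
    h_grid,
    *,
    n_steps: int,
    seed: int,
    dt: float = 0.001,
    refractory_steps: int = 7,
    drive_soma: bool = True,
    transient_steps: int = 0,
    iteration: int = 0,
):
    """Simulate every (P, h) cell once and tabulate soma rate and energy.

    Returns a list of dict rows (iteration, P, h, seed, soma_rate, E,
    E_rel, defined); per-cell seeds derive from (seed, iteration, iP, ih)
    so any single cell can be reproduced in isolation.
    """
    rows = []
    for ip, P in enumerate(p_grid):
        for ih, h in enumerate(h_grid):
            s = cell_seed(seed, iteration, ip, ih)
            params = DynamicsParams(
                P=float(P), h=float(h), dt=dt,
                refractory_steps=refractory_steps, n_steps=n_steps,
                seed=s, drive_soma=drive_soma,
                transient_steps=transient_steps,
            )
            counts = simulate(m, params)
            e = energy(counts)
            rows.append({
                "iteration": iteration,
                "P": float(P),
                "h": float(h),
                "seed": s,
                "soma_rate": firing_rate(counts, m.soma_id),
                "E": e.E,
                "E_rel": e.E_rel,
                "defined": e.defined,
            })
    return rows


def parameter_space_mean(
    m: Morphology,
    quantity: str,
    *,
    p_grid=None,
    h_grid=None,
    n_steps: int,
    seed: int,
    **sim_kwargs,
) -> tuple[float, int]:
    """Unweighted mean of E or E_rel over the (P, h) parameter box
    0.5 <= P <= 1, 1e-2 <= h <= 1e3 (or a supplied grid).

    Cells where the quantity is undefined (the soma never fired) are
    excluded; returns (mean, number of excluded cells).
    """
    if quantity not in ("E", "E_rel"):
        raise ValueError("quantity must be 'E' or 'E_rel'")
    if p_grid is None:
        p_grid = default_p_grid()
    if h_grid is None:
        h_grid = default_h_grid()
    rows = energy_grid(m, p_grid, h_grid, n_steps=n_steps, seed=seed,
                       **sim_kwargs)
    return mean_over_cells(rows, quantity)


def mean_over_cells(rows, quantity: str) -> tuple[float, int]:
    """Mean of a per-cell quantity over the cells where it is defined."""
    vals = [r[quantity] for r in rows if r["defined"]]
    n_excluded = len(rows) - len(vals)
    if not vals:
        raise ValueError("quantity undefined in every cell")
    return float(np.mean(vals)), n_excluded


def classify(
    n_somatic_branches: int,
    soma_centrality: float,
    centrality_threshold: float = 0.3,
) -> str:
    """Branch-centrality functional type of a neuron.

    Type 2: exactly one somatic stem.  Type T (transitional): bitufted,
    exactly two stems.  Otherwise the centrality of the soma separates
    energy-efficient Type 1 (central soma) from inefficient Type 3; the
    boundary defaults to 0.3, where the relative energy consumption
    empirically crosses 1 along pruning trajectories.
    """
    if n_somatic_branches == 1:
        return "Type 2"
    if n_somatic_branches == 2:
        return "Type T"
    return "Type 1" if soma_centrality >= centrality_threshold else "Type 3"
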