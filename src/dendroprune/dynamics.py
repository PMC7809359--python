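"""Excitable dynamics on the compartmental tree.

Each compartment is a three-stage probabilistic cellular automaton with
synchronous update: susceptible -> active -> refractory (a fixed number of
steps) -> susceptible.  A susceptible compartment becomes active either
through external drive (stochastic synaptic input at rate h, giving a
per-step probability r = 1 - exp(-h dt)) or by propagation from each
active tree-neighbor independently with probability P; with k active
neighbors the combined activation probability is
1 - (1 - r_eff) (1 - P)**k.

Timing convention: a compartment active at step t is refractory for steps
t+1 .. t+R and susceptible again at step t+R+1, where it may be activated
no earlier than the update producing step t+R+2.  The minimum inter-spike
interval is therefore R + 2 steps and the maximum rate 1/((R + 2) dt)
(111.1 Hz at the defaults dt = 1 ms, R = 7).

State encoding in :class:`StateVector` arrays: 0 = susceptible,
1 = active, -k = refractory with k steps remaining (k = 1..R).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse

from .morphology import Morphology

__all__ = [
    "SUSCEPTIBLE",
    "ACTIVE",
    "DynamicsParams",
    "SpikeCounts",
    "external_activation_prob",
    "node_order",
    "adjacency_matrix",
    "step",
    "simulate",
    "firing_rate",
]

SUSCEPTIBLE = 0
ACTIVE = 1


@dataclass(frozen=True)
class DynamicsParams:
    """Parameters of one simulation run.

    P is the signal propagation probability between neighboring
    compartments; h the external (synaptic) input rate in Hz applied per
    the drive policy: ``drive_soma=True`` drives every compartment
    including the soma, ``False`` drives dendritic compartments only.
    """

    P: float
    h: float
    dt: float = 0.001
    refractory_steps: int = 7
    n_steps: int = 100_000
    seed: int = 0
    drive_soma: bool = True
    transient_steps: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.P <= 1.0:
            raise ValueError("P must be in [0, 1]")
        if self.h < 0:
            raise ValueError("h must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.refractory_steps < 0:
            raise ValueError("refractory_steps must be >= 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.transient_steps < 0:
            raise ValueError("transient_steps must be >= 0")


@dataclass(frozen=True)
class SpikeCounts:
    """Per-compartment activation tallies over the counted steps.

    ``ids[0]`` is always the soma; ``counts[j]`` is the number of entries
    into the active state of compartment ``ids[j]``.
    """

    ids: tuple[int, ...]
    counts: np.ndarray
    n_counted_steps: int
    dt: float

    def __getitem__(self, i: int) -> int:
        try:
            j = self.ids.index(i)
        except ValueError:
            raise KeyError(f"unknown compartment id {i}") from None
        return int(self.counts[j])

    @property
    def soma_count(self) -> int:
        return int(self.counts[0])

    @property
    def dendritic_counts(self) -> np.ndarray:
        return self.counts[1:]


def external_activation_prob(h: float, dt: float) -> float:
    """Per-step external activation probability r = 1 - exp(-h dt)."""
    if h < 0:
        raise ValueError("h must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    return float(-np.expm1(-h * dt))


def node_order(m: Morphology) -> list[int]:
    """Canonical compartment ordering for state vectors: soma first
    (index 0 — 'compartment 0 refers to the soma'), then dendritic
    compartments by ascending id."""
    soma = m.soma_id
    return [soma] + sorted(i for i in m.ids() if i != soma)


def adjacency_matrix(m: Morphology, order: list[int] | None = None) -> sparse.csr_matrix:
    """Symmetric 0/1 adjacency of the compartment tree in ``order``."""
    if order is None:
        order = node_order(m)
    index = {i: j for j, i in enumerate(order)}
    rows, cols = [], []
    for i in order:
        c = m[i]
        if c.parent_id is not None:
            rows += [index[i], index[c.parent_id]]
            cols += [index[c.parent_id], index[i]]
    n = len(order)
    data = np.ones(len(rows), dtype=np.int8)
    return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))


def _drive_vector(m: Morphology, params: DynamicsParams,
                  order: list[int]) -> np.ndarray:
    r = external_activation_prob(params.h, params.dt)
    r_eff = np.full(len(order), r)
    if not params.drive_soma:
        r_eff[0] = 0.0
    return r_eff


def step(
    states: np.ndarray,
    m: Morphology,
    params: DynamicsParams,
    rng: np.random.Generator,
    *,
    adj: sparse.csr_matrix | None = None,
    r_eff: np.ndarray | None = None,
) -> np.ndarray:
    """One synchronous update; all transitions read the pre-step state.

    ``adj``/``r_eff`` may be supplied to avoid rebuilding them in a loop.
    """
    order = node_order(m)
    if states.shape != (len(order),):
        raise ValueError(
            f"state vector of length {states.shape} does not match "
            f"morphology with {len(order)} compartments"
        )
    if adj is None:
        adj = adjacency_matrix(m, order)
    if r_eff is None:
        r_eff = _drive_vector(m, params, order)
    return _step_arrays(states, adj, r_eff, params.P,
                        params.refractory_steps, rng)


def _step_arrays(
    states: np.ndarray,
    adj: sparse.csr_matrix,
    r_eff: np.ndarray,
    P: float,
    refractory_steps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    active = states == ACTIVE
    k = adj.dot(active.astype(np.int64))
    p_act = 1.0 - (1.0 - r_eff) * (1.0 - P) ** k
    fires = (states == SUSCEPTIBLE) & (rng.random(states.shape[0]) < p_act)
    nxt = np.where(states < 0, states + 1, SUSCEPTIBLE)
    if refractory_steps > 0:
        nxt = np.where(active, -refractory_steps, nxt)
    nxt[fires] = ACTIVE
    return nxt


def simulate(
    m: Morphology,
    params: DynamicsParams,
    *,
    record_raster: bool = False,
) -> SpikeCounts | tuple[SpikeCounts, np.ndarray]:
    """Run the automaton from the all-susceptible initial condition.

    Runs ``transient_steps`` discarded updates followed by ``n_steps``
    counted updates; activations are tallied per compartment during the
    counted steps only.  Reproducible given ``params.seed``.  With
    ``record_raster=True`` additionally returns the boolean
    (n_steps, n_compartments) activity raster of the counted steps.
    """
    order = node_order(m)
    n = len(order)
    adj = adjacency_matrix(m, order)
    r_eff = _drive_vector(m, params, order)
    rng = np.random.default_rng(params.seed)

    states = np.zeros(n, dtype=np.int64)
    for _ in range(params.transient_steps):
        states = _step_arrays(states, adj, r_eff, params.P,
                              params.refractory_steps, rng)
    counts = np.zeros(n, dtype=np.int64)
    raster = (
        np.zeros((params.n_steps, n), dtype=bool) if record_raster else None
    )
    for t in range(params.n_steps):
        states = _step_arrays(states, adj, r_eff, params.P,
                              params.refractory_steps, rng)
        active = states == ACTIVE
        counts += active
        if raster is not None:
            raster[t] = active
    result = SpikeCounts(
        ids=tuple(order),
        counts=counts,
        n_counted_steps=params.n_steps,
        dt=params.dt,
    )
    if record_raster:
        return result, raster
    return result


def firing_rate(counts: SpikeCounts, i: int, dt: float | None = None) -> float:
    """Mean firing rate (Hz) of compartment ``i``: S_i / (steps * dt)."""
    if dt is None:
        dt = counts.dt
    return counts[i] / (counts.n_counted_steps * dt)
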