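"""Exact stationary behaviour of tiny automata by exhaustive enumeration.

For morphologies with a handful of compartments the synchronous update is
a finite Markov chain over (refractory_steps + 2) ** n joint states.  This
module enumerates that chain, restricted to the states reachable from the
all-susceptible initial condition, and solves for its stationary
distribution.  It shares no code with the simulator's update loop and
serves as the independent oracle against which long simulations are
checked.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from .dynamics import DynamicsParams, external_activation_prob, node_order
from .morphology import Morphology

__all__ = ["stationary_occupancy", "stationary_rates"]


def _transitions(state, neighbors, p_drive, P, R):
    """All successor states of a joint state with their probabilities.

    Per-node rules: active -> refractory(R) (or susceptible if R = 0);
    refractory(k) -> refractory(k-1); susceptible -> active with
    probability 1 - (1 - r)(1 - P)**k_active_neighbors, else susceptible.
    """
    n = len(state)
    fixed = []
    free = []  # (index, p_activate)
    for i in range(n):
        s = state[i]
        if s == 1:
            fixed.append((i, -R if R > 0 else 0))
        elif s < 0:
            fixed.append((i, s + 1))
        else:
            k = sum(1 for j in neighbors[i] if state[j] == 1)
            p = 1.0 - (1.0 - p_drive[i]) * (1.0 - P) ** k
            free.append((i, p))
    base = [0] * n
    for i, v in fixed:
        base[i] = v
    out = []
    for choice in product([0, 1], repeat=len(free)):
        prob = 1.0
        nxt = list(base)
        for (i, p), fire in zip(free, choice):
            prob *= p if fire else (1.0 - p)
            nxt[i] = 1 if fire else 0
        if prob > 0.0:
            out.append((tuple(nxt), prob))
    return out


def stationary_occupancy(
    m: Morphology, params: DynamicsParams
) -> dict[int, dict[int, float]]:
    """Stationary per-compartment state occupancies of the exact chain.

    Returns {compartment id: {state code: probability}} with state codes as
    in :mod:`dendroprune.dynamics` (0 susceptible, 1 active, -k refractory).
    Intended for n <= 3 compartments; the joint state space grows as
    (refractory_steps + 2) ** n.
    """
    order = node_order(m)
    n = len(order)
    if (params.refractory_steps + 2) ** n > 20000:
        raise ValueError("joint state space too large for enumeration")
    index = {i: j for j, i in enumerate(order)}
    neighbors = [
        [index[j] for j in m.neighbors(i)] for i in order
    ]
    r = external_activation_prob(params.h, params.dt)
    p_drive = [r] * n
    if not params.drive_soma:
        p_drive[0] = 0.0
    R = params.refractory_steps

    start = tuple([0] * n)
    states = {start: 0}
    frontier = [start]
    edges = []  # (from, to, prob)
    while frontier:
        s = frontier.pop()
        for t, p in _transitions(s, neighbors, p_drive, params.P, R):
            if t not in states:
                states[t] = len(states)
                frontier.append(t)
            edges.append((states[s], states[t], p))

    ns = len(states)
    T = np.zeros((ns, ns))
    for a, b, p in edges:
        T[a, b] += p
    # stationary row vector: pi T = pi, sum pi = 1 (least squares with the
    # normalization constraint appended)
    A = np.vstack([T.T - np.eye(ns), np.ones(ns)])
    b = np.zeros(ns + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()

    occ: dict[int, dict[int, float]] = {i: {} for i in order}
    for s, idx in states.items():
        for j, code in enumerate(s):
            d = occ[order[j]]
            d[code] = d.get(code, 0.0) + pi[idx]
    return occ


def stationary_rates(m: Morphology, params: DynamicsParams) -> dict[int, float]:
    """Exact stationary firing rate (Hz) of each compartment: because the
    active state lasts exactly one step, the rate is the stationary
    probability of being active divided by dt."""
    occ = stationary_occupancy(m, params)
    return {i: occ[i].get(1, 0.0) / params.dt for i in occ}
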