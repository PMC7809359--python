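"""Synthetic morphologies with known properties.

Chains, stars, regular (Cayley) trees and random recursive-attachment
trees, all emitted as valid single-soma morphologies that round-trip
through SWC.  Geometry is decorative: segments get unit length along
coordinate axes and unit radii, because the dynamics depend on topology
only.

Also provides the closed-form firing-rate oracle for an isolated driven
compartment, used throughout the test suite as an independent check on the
simulator.
"""

from __future__ import annotations

import math

import numpy as np

from .morphology import Compartment, Morphology

__all__ = [
    "make_chain",
    "make_star",
    "make_cayley",
    "make_random_tree",
    "make_demo_pyramidal",
    "isolated_rate_oracle",
]


class _Builder:
    """Accumulates compartments with sequential ids; soma is id 1."""

    def __init__(self) -> None:
        self.comps = [
            Compartment(1, "soma", np.zeros(3), 1.0, None)
        ]

    @property
    def soma(self) -> int:
        return 1

    def add(self, parent: int, structure: str = "basal") -> int:
        i = len(self.comps) + 1
        pos = self.comps[parent - 1].position + np.array([1.0, 0.0, 0.0])
        self.comps.append(Compartment(i, structure, pos, 1.0, parent))
        return i

    def chain(self, parent: int, length: int, structure: str = "basal") -> int:
        node = parent
        for _ in range(length):
            node = self.add(node, structure)
        return node

    def cayley(self, parent: int, branching: int, depth: int,
               structure: str = "basal") -> None:
        if depth == 0:
            return
        for _ in range(branching):
            child = self.add(parent, structure)
            self.cayley(child, branching, depth - 1, structure)

    def build(self) -> Morphology:
        return Morphology(c.copy() for c in self.comps)


def make_chain(n: int, soma: str = "end") -> Morphology:
    """Soma plus a path of ``n`` dendritic compartments.

    ``soma='end'`` puts the soma at one end (a one-dimensional network of
    coupled excitable units); ``soma='center'`` splits the path into two
    stems of ``ceil(n/2)`` and ``floor(n/2)`` compartments.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    b = _Builder()
    if soma == "end":
        b.chain(b.soma, n)
    elif soma == "center":
        b.chain(b.soma, (n + 1) // 2)
        b.chain(b.soma, n // 2)
    else:
        raise ValueError(f"unknown soma placement {soma!r}")
    return b.build()


def make_star(arms: int, arm_length: int) -> Morphology:
    """Soma at the center of ``arms`` identical paths of ``arm_length``."""
    if arms < 0 or arm_length < 0:
        raise ValueError("arms and arm_length must be >= 0")
    b = _Builder()
    for _ in range(arms):
        b.chain(b.soma, arm_length)
    return b.build()


def make_cayley(branching: int, depth: int) -> Morphology:
    """Regular tree: the soma and every internal compartment have
    ``branching`` children, down to ``depth`` levels below the soma.

    Total dendritic compartments: branching * (branching**depth - 1) /
    (branching - 1).
    """
    if branching < 2 or depth < 1:
        raise ValueError("need branching >= 2 and depth >= 1")
    b = _Builder()
    b.cayley(b.soma, branching, depth)
    return b.build()


def make_random_tree(n: int, seed: int) -> Morphology:
    """Random recursive-attachment tree: compartment k's parent is drawn
    uniformly from the soma and the k-1 compartments added before it.
    Reproducible given ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    b = _Builder()
    ids = [b.soma]
    for _ in range(n):
        parent = ids[rng.integers(len(ids))]
        ids.append(b.add(parent))
    return b.build()


def make_demo_pyramidal(
    n_basal: int = 6,
    basal_depth: int = 4,
    trunk_length: int = 12,
    tuft_depth: int = 6,
) -> Morphology:
    """Deterministic pyramidal-like morphology for desk-scale studies.

    Mimics the structural narrative of an aging pyramidal cell: ``n_basal``
    shallow binary basal subtrees that recede early under pruning, plus one
    apical stem — a trunk of ``trunk_length`` compartments carrying a
    binary tuft of ``tuft_depth`` levels — that retracts last.  With the
    defaults: 228 dendritic compartments, 7 somatic stems; under iterative
    terminal pruning the stem count drops to 1 at iteration ``basal_depth``,
    the last bifurcation disappears at iteration ``tuft_depth``, and the
    neuron is fully pruned at iteration ``trunk_length + tuft_depth``.
    """
    b = _Builder()
    for _ in range(n_basal):
        stem = b.add(b.soma, "basal")
        b.cayley(stem, 2, basal_depth - 1, "basal")
    top = b.chain(b.soma, trunk_length, "apical")
    b.cayley(top, 2, tuft_depth, "apical")
    return b.build()


def isolated_rate_oracle(
    h: float, dt: float = 0.001, refractory_steps: int = 7
) -> float:
    """Exact mean firing rate (Hz) of a single externally driven compartment.

    The renewal cycle under the adopted timing convention is 1 active step,
    ``refractory_steps`` refractory steps, and a geometric wait (mean 1/r
    steps, r = 1 - exp(-h dt)) in the susceptible state before the next
    activation, giving

        F(h) = 1 / ((refractory_steps + 1 + 1/r) * dt)

    which is 0 at h = 0 and saturates at 1/((refractory_steps + 2) dt)
    (111.1 Hz at the defaults) as h grows.
    """
    if h < 0:
        raise ValueError("h must be >= 0")
    if h == 0:
        return 0.0
    r = -math.expm1(-h * dt)
    return 1.0 / ((refractory_steps + 1 + 1.0 / r) * dt)
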