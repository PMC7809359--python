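"""Compartmental neuronal morphologies.

A morphology is a rooted tree of compartments, read from an SWC
reconstruction or built synthetically.  Each compartment is one SWC sample
point; unbranched runs are never resampled or merged, so compartment counts
correspond to raw reconstruction points.  Geometry (positions, radii) is
carried through I/O but never influences the dynamics, which are purely
topological.

The canonical preprocessing pipeline before any analysis is::

    m = load_swc(path)
    m = collapse_soma(m)   # multi-point somas become a single compartment
    m = strip_axon(m)      # the model concerns dendrites and soma only

after which the tree is rooted at a unique soma compartment and every other
compartment is dendritic.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "Compartment",
    "Morphology",
    "MorphometricSummary",
    "SwcError",
    "SwcParseError",
    "SwcStructureError",
    "load_swc",
    "loads_swc",
    "write_swc",
    "dumps_swc",
    "collapse_soma",
    "strip_axon",
    "summarize",
    "eccentricity",
    "all_eccentricities",
    "soma_centrality",
]

#: SWC structure-type codes (NeuroMorpho standardized dialect).
STRUCTURE_CODES = {1: "soma", 2: "axon", 3: "basal", 4: "apical"}
STRUCTURE_LABELS = {"soma": 1, "axon": 2, "basal": 3, "apical": 4, "other": 5}

DENDRITIC = frozenset({"basal", "apical", "other"})


class SwcError(ValueError):
    """Base class for SWC reading problems."""


class SwcParseError(SwcError):
    """A line could not be parsed as an SWC sample point."""


class SwcStructureError(SwcError):
    """The sample points do not form a valid tree."""


@dataclass
class Compartment:
    """One node of the compartmental tree (= one SWC sample point)."""

    id: int
    structure: str
    position: np.ndarray
    radius: float
    parent_id: int | None
    children: list[int] = field(default_factory=list)

    def copy(self) -> "Compartment":
        return Compartment(
            self.id,
            self.structure,
            np.array(self.position, dtype=float),
            self.radius,
            self.parent_id,
            list(self.children),
        )


class Morphology:
    """An id-indexed tree of compartments with a designated root.

    Parent/child links are kept consistent on construction; children are
    ordered by id so that all derived quantities are deterministic under
    permutation of the input line order.
    """

    def __init__(self, compartments: Iterable[Compartment]):
        self.compartments: dict[int, Compartment] = {}
        for c in compartments:
            if c.id in self.compartments:
                raise SwcStructureError(f"duplicate compartment id {c.id}")
            self.compartments[c.id] = c
        self._link()

    def _link(self) -> None:
        roots = []
        for c in self.compartments.values():
            c.children = []
        for c in self.compartments.values():
            if c.parent_id is None:
                roots.append(c.id)
                continue
            if c.parent_id == c.id:
                raise SwcStructureError(
                    f"compartment {c.id} lists itself as its parent"
                )
            parent = self.compartments.get(c.parent_id)
            if parent is None:
                raise SwcStructureError(
                    f"compartment {c.id} refers to nonexistent parent {c.parent_id}"
                )
            parent.children.append(c.id)
        for c in self.compartments.values():
            c.children.sort()
        if not roots:
            raise SwcStructureError("no root compartment (cycle through every node)")
        if len(roots) > 1:
            raise SwcStructureError(f"multiple roots: {sorted(roots)}")
        self.root_id: int = roots[0]
        # reachability from the root rules out cycles in non-root components
        seen = set()
        stack = [self.root_id]
        while stack:
            i = stack.pop()
            seen.add(i)
            stack.extend(self.compartments[i].children)
        if len(seen) != len(self.compartments):
            raise SwcStructureError(
                "graph is not a tree (cycle or disconnected component detected)"
            )

    # -- basic queries ------------------------------------------------------

    def __len__(self) -> int:
        return len(self.compartments)

    def __contains__(self, i: int) -> bool:
        return i in self.compartments

    def __getitem__(self, i: int) -> Compartment:
        return self.compartments[i]

    def ids(self) -> Iterator[int]:
        return iter(self.compartments)

    @property
    def soma_id(self) -> int:
        """Id of the unique soma compartment (requires a collapsed soma)."""
        soma = [c.id for c in self.compartments.values() if c.structure == "soma"]
        if len(soma) != 1:
            raise SwcStructureError(
                f"expected exactly one soma compartment, found {len(soma)}; "
                "call collapse_soma first"
            )
        return soma[0]

    def dendritic_ids(self) -> list[int]:
        return [
            c.id for c in self.compartments.values() if c.structure in DENDRITIC
        ]

    def terminal_ids(self) -> list[int]:
        """Compartments without children ('a compartment that does not have
        any children is considered a terminus')."""
        return [c.id for c in self.compartments.values() if not c.children]

    def neighbors(self, i: int) -> list[int]:
        c = self.compartments[i]
        out = list(c.children)
        if c.parent_id is not None:
            out.append(c.parent_id)
        return out

    def copy(self) -> "Morphology":
        return Morphology(c.copy() for c in self.compartments.values())

    def bfs_order(self) -> list[int]:
        order = []
        q = deque([self.root_id])
        while q:
            i = q.popleft()
            order.append(i)
            q.extend(self.compartments[i].children)
        return order


@dataclass(frozen=True)
class MorphometricSummary:
    """Counts and soma centrality of a collapsed, axon-stripped morphology.

    ``n_compartments`` counts dendritic compartments only (the soma is
    compartment 0 of the dynamics and is excluded, matching the indexing
    of the energy measures); ``n_compartments_with_soma`` is exposed
    alongside for bookkeeping against external tables.
    """

    n_compartments: int
    n_bifurcations: int
    n_somatic_branches: int
    soma_centrality: float
    n_compartments_with_soma: int

    def as_dict(self) -> dict:
        return {
            "n_compartments": self.n_compartments,
            "n_bifurcations": self.n_bifurcations,
            "n_somatic_branches": self.n_somatic_branches,
            "soma_centrality": self.soma_centrality,
            "n_compartments_with_soma": self.n_compartments_with_soma,
        }


# ---------------------------------------------------------------------------
# SWC I/O


def loads_swc(text: str, source: str = "<string>") -> Morphology:
    """Parse SWC text (7 whitespace-separated columns, '#' comments)."""
    comps: list[Compartment] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SwcParseError(
                f"{source}:{lineno}: expected 7 columns, got {len(parts)}"
            )
        try:
            i = int(parts[0])
            code = int(parts[1])
            x, y, z, r = (float(v) for v in parts[2:6])
            parent = int(parts[6])
        except ValueError as exc:
            raise SwcParseError(f"{source}:{lineno}: {exc}") from None
        if i <= 0:
            raise SwcParseError(f"{source}:{lineno}: sample id must be positive")
        comps.append(
            Compartment(
                id=i,
                structure=STRUCTURE_CODES.get(code, "other"),
                position=np.array([x, y, z], dtype=float),
                radius=r,
                parent_id=None if parent == -1 else parent,
            )
        )
    if not comps:
        raise SwcError(f"{source}: no SWC data lines")
    return Morphology(comps)


def load_swc(path: str | Path) -> Morphology:
    """Read an SWC reconstruction file into a :class:`Morphology`."""
    path = Path(path)
    return loads_swc(path.read_text(), source=str(path))


def dumps_swc(m: Morphology, comment: str | None = None) -> str:
    lines = []
    if comment:
        for c in comment.splitlines():
            lines.append(f"# {c}")
    for i in m.bfs_order():
        c = m[i]
        code = STRUCTURE_LABELS.get(c.structure, 5)
        x, y, z = c.position
        parent = -1 if c.parent_id is None else c.parent_id
        lines.append(f"{c.id} {code} {x:.6g} {y:.6g} {z:.6g} {c.radius:.6g} {parent}")
    return "\n".join(lines) + "\n"


def write_swc(m: Morphology, path: str | Path, comment: str | None = None) -> None:
    Path(path).write_text(dumps_swc(m, comment=comment))


# ---------------------------------------------------------------------------
# Soma collapse and axon removal


def collapse_soma(m: Morphology) -> Morphology:
    """Merge all contiguous soma-labeled points into a single compartment.

    The merged soma sits at the centroid of the merged points; dendritic
    (and axonal) children of any merged point re-attach to it, and the tree
    is re-rooted at the soma.  Radii of merged points are averaged but are
    decorative only.
    """
    soma_ids = [c.id for c in m.compartments.values() if c.structure == "soma"]
    if not soma_ids:
        raise SwcStructureError(
            "no soma-labeled compartment; designate a root by relabeling one "
            "compartment as soma (type code 1)"
        )
    soma_set = set(soma_ids)
    # contiguity: soma points must form one connected subgraph
    seen = {soma_ids[0]}
    q = deque([soma_ids[0]])
    while q:
        i = q.popleft()
        for j in m.neighbors(i):
            if j in soma_set and j not in seen:
                seen.add(j)
                q.append(j)
    if seen != soma_set:
        raise SwcStructureError("soma-labeled compartments are not contiguous")

    new_id = min(soma_ids)
    centroid = np.mean([m[i].position for i in soma_ids], axis=0)
    radius = float(np.mean([m[i].radius for i in soma_ids]))

    # contract the soma set to one node, then re-root the tree at it
    remap = {i: (new_id if i in soma_set else i) for i in m.ids()}
    adjacency: dict[int, set[int]] = {}
    for c in m.compartments.values():
        if c.parent_id is None:
            continue
        a, b = remap[c.id], remap[c.parent_id]
        if a == b:
            continue
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)
    adjacency.setdefault(new_id, set())

    parent: dict[int, int | None] = {new_id: None}
    order = [new_id]
    q = deque([new_id])
    while q:
        i = q.popleft()
        for j in sorted(adjacency.get(i, ())):
            if j not in parent:
                parent[j] = i
                order.append(j)
                q.append(j)

    comps = []
    for i in order:
        if i == new_id:
            comps.append(
                Compartment(new_id, "soma", centroid, radius, None)
            )
        else:
            c = m[i]
            comps.append(
                Compartment(
                    c.id, c.structure, np.array(c.position), c.radius, parent[i]
                )
            )
    return Morphology(comps)


def strip_axon(m: Morphology) -> Morphology:
    """Remove axon-labeled compartments and all their descendants."""
    drop = set()
    for i in m.bfs_order():
        c = m[i]
        if c.structure == "axon" or (c.parent_id in drop):
            drop.add(i)
    if m.root_id in drop:
        raise SwcStructureError("cannot strip the axon: the root is axon-labeled")
    if not drop:
        return m.copy()
    return Morphology(
        m[i].copy() for i in m.bfs_order() if i not in drop
    )


# ---------------------------------------------------------------------------
# Morphometrics


def eccentricity(m: Morphology, i: int) -> int:
    """Tree eccentricity of compartment ``i``: the number of edges to the
    farthest compartment (for any tree with >= 2 nodes this farthest
    compartment is a terminal one).  A lone compartment has eccentricity 0.
    """
    if i not in m:
        raise KeyError(f"unknown compartment id {i}")
    dist = _bfs_distances(m, i)
    return max(dist.values())


def _bfs_distances(m: Morphology, start: int) -> dict[int, int]:
    dist = {start: 0}
    q = deque([start])
    while q:
        i = q.popleft()
        for j in m.neighbors(i):
            if j not in dist:
                dist[j] = dist[i] + 1
                q.append(j)
    return dist


def all_eccentricities(m: Morphology) -> dict[int, int]:
    """Eccentricity of every compartment in O(n) via the double-BFS
    diameter trick: for a tree, ecc(v) = max(d(v, a), d(v, b)) where (a, b)
    is any diameter pair."""
    start = m.root_id
    d0 = _bfs_distances(m, start)
    a = max(d0, key=d0.__getitem__)
    da = _bfs_distances(m, a)
    b = max(da, key=da.__getitem__)
    db = _bfs_distances(m, b)
    return {i: max(da[i], db[i]) for i in m.ids()}


def soma_centrality(m: Morphology) -> float:
    """Min-max-normalized inverse eccentricity of the soma.

    Returns (ecc_max - ecc_soma) / (ecc_max - ecc_min) over the
    eccentricities of all compartments, so the most central compartments
    (smallest eccentricity) score 1 and the least central score 0.  When
    every compartment is equally central (soma-only morphology, perfect
    symmetry) the convention is 1.
    """
    ecc = all_eccentricities(m)
    soma = m.soma_id
    lo, hi = min(ecc.values()), max(ecc.values())
    if hi == lo:
        return 1.0
    return (hi - ecc[soma]) / (hi - lo)


def summarize(m: Morphology) -> MorphometricSummary:
    """Morphometrics of a collapsed, axon-stripped morphology."""
    soma = m.soma_id
    dend = m.dendritic_ids()
    n_bif = sum(1 for i in dend if len(m[i].children) >= 2)
    n_stems = sum(1 for j in m[soma].children if m[j].structure in DENDRITIC)
    return MorphometricSummary(
        n_compartments=len(dend),
        n_bifurcations=n_bif,
        n_somatic_branches=n_stems,
        soma_centrality=soma_centrality(m),
        n_compartments_with_soma=len(dend) + 1,
    )
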