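"""Iterative dendritic pruning — the aging model.

Each pruning iteration simultaneously removes every terminal dendritic
compartment (a compartment without children); the soma is exempt even when
childless.  Iteration 0 is the intact morphology and iteration k is the
state after k passes.  Repeating until no dendritic compartment remains
yields a trajectory of morphometric summaries together with three landmark
iterations:

* ``single_stem_iteration`` — first iteration with exactly one somatic
  stem (undefined if the stem count ever skips from >= 2 straight to 0);
* ``last_bifurcation_iteration`` — first iteration with no dendritic
  bifurcation while at least one dendritic compartment remains;
* ``fully_pruned_iteration`` — first iteration with no dendritic
  compartments at all.

Extension hooks deliberately not implemented here: stochastic removal of a
fixed number of terminal compartments per iteration, and removal of whole
branches at a time; both are natural variants of :func:`prune_once` that
callers can build from :meth:`Morphology.terminal_ids`.
"""

from __future__ import annotations

from dataclasses import dataclass

from .morphology import (
    DENDRITIC,
    Morphology,
    MorphometricSummary,
    summarize,
)

__all__ = ["PruneTrajectory", "prune_once", "prune_trajectory", "snapshot_at"]


@dataclass(frozen=True)
class PruneTrajectory:
    """Per-iteration morphometrics of a full pruning run."""

    per_iteration: list[MorphometricSummary]
    single_stem_iteration: int | None
    last_bifurcation_iteration: int | None
    fully_pruned_iteration: int

    def __len__(self) -> int:
        return len(self.per_iteration)

    def summary_at(self, iteration: int) -> MorphometricSummary:
        return self.per_iteration[iteration]


def prune_once(m: Morphology) -> Morphology:
    """Remove all terminal dendritic compartments simultaneously.

    Ids, labels and all surviving compartments are unchanged; a soma-only
    morphology is returned as a copy of itself.
    """
    doomed = {
        i for i in m.terminal_ids() if m[i].structure in DENDRITIC
    }
    return Morphology(
        m[i].copy() for i in m.bfs_order() if i not in doomed
    )


def prune_trajectory(m: Morphology) -> PruneTrajectory:
    """Prune until no dendritic compartment remains, recording morphometrics
    at every iteration (iteration 0 = the intact morphology)."""
    summaries = [summarize(m)]
    current = m
    while summaries[-1].n_compartments > 0:
        current = prune_once(current)
        summaries.append(summarize(current))

    single_stem = None
    for k, s in enumerate(summaries):
        if s.n_somatic_branches == 1:
            single_stem = k
            break
        if s.n_somatic_branches == 0:
            break  # skipped from >= 2 to 0: landmark undefined
    last_bif = None
    for k, s in enumerate(summaries):
        if s.n_bifurcations == 0 and s.n_compartments >= 1:
            last_bif = k
            break
    fully = len(summaries) - 1
    return PruneTrajectory(
        per_iteration=summaries,
        single_stem_iteration=single_stem,
        last_bifurcation_iteration=last_bif,
        fully_pruned_iteration=fully,
    )


def snapshot_at(m: Morphology, iteration: int) -> Morphology:
    """The morphology after exactly ``iteration`` pruning passes."""
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    current = m.copy()
    for k in range(iteration):
        if not current.dendritic_ids():
            raise ValueError(
                f"iteration {iteration} is beyond full pruning (reached at {k})"
            )
        current = prune_once(current)
    return current
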