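# dendroprune

Dendritic pruning and excitable-compartment dynamics on neuronal
morphologies.

Aging neurons lose dendritic complexity: terminal branches recede, basal
dendrites disappear, and the apical arbor retracts toward its main shaft.
`dendroprune` is a desk-scale simulation tool for asking what that
structural decline does to single-neuron function. It is aimed at
computational neuroscientists who want to run topology-only excitable
dynamics on real reconstructions (SWC files, e.g. from NeuroMorpho.org)
or on synthetic trees, prune them iteratively, and track how energy
consumption, energy efficiency, and dynamic range degrade along the
pruning trajectory.

## Model

**Morphology.** A neuron is a rooted tree of compartments — one SWC
sample point each, the soma collapsed to a single compartment, axons
removed. Geometry is carried through I/O but the dynamics are purely
topological.

**Pruning (aging).** Each pruning iteration simultaneously removes every
terminal dendritic compartment (any compartment without children; the
soma is exempt). Iteration 0 is the intact neuron. Three landmark
iterations summarize a trajectory: the first with a single somatic stem,
the first with no dendritic bifurcation, and full pruning.

**Dynamics.** Each compartment is a three-stage probabilistic cellular
automaton with synchronous update: susceptible → active → refractory
(R = 7 steps of δt = 1 ms) → susceptible. A susceptible compartment
activates externally with per-step probability r = 1 − exp(−h·δt)
(stochastic synaptic drive at rate h) or from each active neighbor
independently with propagation probability P; with k active neighbors the
combined probability is 1 − (1 − r)(1 − P)^k. The maximum firing rate
under this timing is 1/((R + 2)·δt) ≈ 111.1 Hz.

**Measures.** With S_i the spike tally of compartment i (S_0 = soma) and
N dendritic compartments:

- response function F(h): mean soma firing rate vs. input rate h;
- dynamic range Δ = 10·log₁₀(h₉₀/h₁₀), the width in input decades mapped
  between 10% and 90% of the curve's maximum rate;
- energy consumption E = Σᵢ Sᵢ / S₀ and relative energy consumption
  E_rel = E/N (E_rel < 1 = energy-efficient);
- soma centrality: min–max-normalized inverse tree eccentricity
  (1 = most central compartment, 0 = least);
- a branch–centrality classification (Type 1 efficient, Type 2
  single-stem, Type T bitufted, Type 3 inefficient).

## Worked example

```python
import dendroprune as dp

neuron = dp.make_demo_pyramidal()          # 228-compartment pyramidal-like tree
print(dp.summarize(neuron))

traj = dp.prune_trajectory(neuron)
print("single stem at", traj.single_stem_iteration,
      "| last bifurcation at", traj.last_bifurcation_iteration,
      "| fully pruned at", traj.fully_pruned_iteration)

params = dp.DynamicsParams(P=0.8, h=1.0, n_steps=20_000, seed=1)
counts = dp.simulate(neuron, params)
e = dp.energy(counts)
print(f"soma rate {dp.firing_rate(counts, neuron.soma_id):.2f} Hz, "
      f"E = {e.E:.2f}, E_rel = {e.E_rel:.3f}")

aged = dp.snapshot_at(neuron, 8)
counts_aged = dp.simulate(aged, dp.DynamicsParams(P=0.8, h=1.0,
                                                  n_steps=20_000, seed=1))
e_aged = dp.energy(counts_aged)
print(f"after 8 pruning iterations: soma rate "
      f"{dp.firing_rate(counts_aged, aged.soma_id):.2f} Hz, "
      f"E = {e_aged.E:.2f}, E_rel = {e_aged.E_rel:.3f}")
```

prints

```
MorphometricSummary(n_compartments=228, n_bifurcations=105, n_somatic_branches=7, soma_centrality=0.36363636363636365, n_compartments_with_soma=229)
single stem at 4 | last bifurcation at 6 | fully pruned at 18
soma rate 31.10 Hz, E = 129.65, E_rel = 0.569
after 8 pruning iterations: soma rate 3.80 Hz, E = 13.21, E_rel = 1.321
```

Read: the intact neuron fires at 31 Hz under weak drive (h = 1 Hz) and is
energy-efficient (E_rel = 0.57 dendritic spikes per compartment per
somatic spike). After eight rounds of terminal pruning only a bare apical
stem remains; total energy consumption has fallen ten-fold (fewer
dendrites means fewer dendritic spikes), but the surviving neuron is
energy-*inefficient* (E_rel = 1.32): its remaining dendrites fire more
often than the soma they are supposed to drive, and the soma rate has
collapsed.

The same pipelines are exposed as a CLI
(`dendroprune synth | prune | simulate | sweep | report`); `sweep` writes
tidy long-format CSVs with per-cell seed provenance and `report` renders
the trajectory plots.

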