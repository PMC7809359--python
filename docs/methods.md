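# Methods

## Compartmental morphologies

A morphology is a rooted tree whose nodes are SWC sample points
(7-column whitespace format; type codes 1 = soma, 2 = axon, 3 = basal,
4 = apical, anything else = other). One sample point = one compartment;
unbranched runs are never resampled, so compartment counts follow the raw
reconstruction. Before any analysis the canonical pipeline is applied:

1. `collapse_soma` — all contiguous soma-labeled points merge into one
   compartment at their centroid (radii of merged points are averaged but
   decorative: the dynamics are purely topological). Children of any
   merged point re-attach to the single soma and the tree is re-rooted
   there. Disjoint soma regions or a missing soma label are hard errors:
   the tool does not repair broken reconstructions.
2. `strip_axon` — axon-labeled compartments and their descendants are
   removed; the model concerns dendrites and soma only.

Morphometrics (`summarize`) then count **dendritic** compartments (the
soma is compartment 0 of the dynamics and excluded from N, matching the
indexing of the energy measures; the soma-inclusive count is exposed
alongside), dendritic bifurcations (≥ 2 children), and somatic stems
(dendritic children of the soma).

**Eccentricity and centrality.** A compartment's eccentricity is the
number of edges to the farthest compartment of the tree — for any tree
with at least two nodes that farthest compartment is a terminal one.
Distances are counted in hops, not µm. All eccentricities are computed in
O(n) by the double-BFS diameter trick (ecc(v) = max of the distances to
the two diameter endpoints), which the test suite cross-checks against
networkx's all-pairs eccentricity on random trees. Soma centrality is the
min–max normalization (ecc_max − ecc_soma)/(ecc_max − ecc_min) over all
compartments, so the least central compartments score 0 and the most
central 1; when every compartment is equally central (a lone soma, a
perfectly symmetric star) the convention is 1.

## Pruning

`prune_once` removes, simultaneously, every dendritic compartment without
children; the soma is exempt even when childless. Iteration 0 is the
intact morphology and iteration k the state after k passes; each nonempty
dendritic forest has at least one terminus, so compartment counts
strictly decrease until exhaustion. Landmarks along a full trajectory:

- `single_stem_iteration`: first iteration with exactly one somatic stem.
  If the stem count skips from ≥ 2 straight to 0 in one pass (equal-height
  stems vanishing together) the landmark is reported as `None` rather
  than invented.
- `last_bifurcation_iteration`: first iteration with zero dendritic
  bifurcations while at least one dendritic compartment remains.
- `fully_pruned_iteration`: first iteration with no dendritic
  compartments. It equals the maximum stem height in compartments, which
  the tests verify against an independent per-node removal-pass recursion.

Stochastic pruning (removing a random subset of termini per pass) and
whole-branch removal are deliberate extension hooks, not implemented;
both are one-line variants over `Morphology.terminal_ids()`.

## Dynamics

Synchronous probabilistic cellular automaton on the compartment tree.
States: susceptible, active, refractory(k) for k = 1..R. Per update, all
transitions are computed from the pre-step state:

- susceptible → active with probability 1 − (1 − r_eff)(1 − P)^k, where
  k is the number of active tree-neighbors (both directions), P the
  propagation probability, and r_eff the external drive probability.
  Multiple simultaneous causes combine as independent attempts.
- active → refractory(R); refractory(k) → refractory(k−1);
  refractory(1) → susceptible, eligible for re-activation only at the
  *next* update.

External drive: r = 1 − exp(−h·δt) per step, with h in Hz and δt = 1 ms.
Defaults R = 7, all-susceptible initial condition, no discarded transient
(configurable). The timing convention fixes the minimum inter-spike
interval at R + 2 steps and the saturated rate at 1/((R + 2)δt) = 111.1 Hz;
an isolated driven compartment is a renewal process with exact mean rate
F(h) = 1/((R + 1 + 1/r)δt), used throughout as a closed-form oracle.

**Drive policy.** By default external input drives every compartment
including the soma (`drive_soma=True`): synaptic drive is modeled as
spatially unspecific, and a fully pruned neuron must still respond so
that trajectories extend to complete pruning. The flag excludes the soma
when the alternative policy is wanted; both are supported and tested.

**Verification.** Besides the closed form, the stationary behaviour of
any ≤ 3-compartment system is computed exactly by enumerating the joint
synchronous Markov chain ((R + 2)^n states, reachable set from
all-susceptible, stationary distribution by linear solve) in
`dendroprune.oracles`; this shares no code with the simulator. Long
simulations agree within three batch-means standard errors on rates and
on susceptible/active/refractory occupancies.

**Reproducibility.** One `numpy` PCG64 generator per simulation, seeded
from `DynamicsParams.seed`. Grid sweeps derive one seed per
(iteration, P-index, h-index) cell through `SeedSequence`, recorded in
the output rows, so any cell reruns in isolation bit-identically.

## Derived measures

**Response function and dynamic range.** F(h) is the soma's mean rate,
one independent simulation per h on a log-spaced grid. F_max is the
maximum of the *sampled* curve (well defined for every curve; at
saturating h it approximates the theoretical ceiling). h10 and h90 are
located at the first upward crossing of 0.1·F_max / 0.9·F_max by linear
interpolation of F against log₁₀ h, and Δ = 10·log₁₀(h₉₀/h₁₀). A curve
that never leaves zero has undefined Δ; a curve already above the 10%
level at the smallest sampled h reports an out-of-grid bound instead of
extrapolating. On smooth curves Δ moves by < 0.2 when the grid density
doubles.

**Energy.** E = Σ_{i=1..N} S_i / S_0, E_rel = E/N. When the soma never
fires (or N = 0) both are flagged undefined — not infinite — and such
cells are excluded (and counted) in parameter-space averages.
Parameter-space means are unweighted arithmetic means over the box
0.5 ≤ P ≤ 1 (11 values by default) × 10⁻² ≤ h ≤ 10³ Hz (log-spaced,
10 points/decade by default); the ranges are fixed, the resolution is a
parameter.

**Classification.** Type 2 = one somatic stem; Type T = bitufted (two
stems); otherwise soma centrality ≥ 0.3 → Type 1 (efficient), < 0.3 →
Type 3 (inefficient). The 0.3 boundary is where the parameter-space mean
E_rel empirically first exceeds 1 along pruning trajectories; it is a
configurable parameter, not a law.

## Synthetic morphologies and the demo neuron

Generators: chains (soma at end or center), stars, regular trees with
fixed branching, and seeded random recursive-attachment trees — each with
closed-form counts the tests assert — plus `make_demo_pyramidal`, the
deterministic pyramidal-like morphology used for desk-scale studies: six
basal binary subtrees of depth 4 and one apical stem (trunk of 12
compartments, binary tuft of depth 6), 228 dendritic compartments and 7
somatic stems in total. Its construction encodes the structural narrative
of pyramidal-cell aging — basal dendrites recede first, the apical tuft
retracts onto the main shaft — and makes every landmark hand-derivable:
stems drop to 1 at iteration 4, the last bifurcation disappears at 6,
and the neuron is fully pruned at 18.

What the generators do *not* emulate: realistic branch statistics (Sholl
profiles, branch angles, segment lengths), reconstruction noise, or the
sheer size of real arbors (thousands of compartments). Passing tests on
these trees therefore validate the algorithms and the direction and shape
of the aging trends, not the numerical values any particular biological
reconstruction would produce.

## Study sizes and numerical choices

Desk-scale defaults, chosen once: sweeps use 6 P-values × 13 log-spaced
h-values over the standard box with 20,000 steps per cell in the
acceptance script (≈ 4–5 min on one core), and 4 × 9 cells at 6,000 steps
in the test suite; oracle-equivalence tests run 150,000–200,000 steps on
1–2 compartments where Monte-Carlo error, not cost, is the constraint.
Statistical assertions use three batch-means standard errors (50
batches), robust to the autocorrelation the refractory period induces.
With these sizes the qualitative results are stable across seeds: mean E
decreases monotonically with pruning (Spearman ρ = −1 at the default
conditions), mean E_rel rises past 1 and peaks a few iterations after the
single-stem landmark before declining on the bare stem, Δ shrinks with
pruning and grows with P, and the first crossing into inefficiency occurs
at soma centrality below 0.3.

## Known limitations

- Topology-only dynamics: no cable properties, no geometry-dependent
  propagation, no synapse placement, no inhibition or plasticity, single
  neurons only.
- Dynamic range is undefined on all-zero curves and reported as
  out-of-grid when the sampled h-range does not bracket the 10% or 90%
  crossing; widen the grid rather than trust extrapolation.
- The exact Markov oracle is exponential in compartment count and
  restricted to ≤ 3 compartments by design.
- Real SWC reconstructions vary in dialect; files whose sample points do
  not form a single tree with a contiguous soma are rejected with a
  structural error rather than repaired.
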