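# Methods

This note documents the models implemented in `commarch`, the
parameter defaults and why they were chosen, what the synthetic data
emulate (and do not), and the numerical conventions that make results
deterministic and testable.

## Community architecture: the two scores

**Segregation.** A network's segregation score is the Newman–Girvan
modularity `Q = Σ_c [L_c/m − γ(d_c/2m)²]` of the best partition found
by Louvain at resolution γ = 1. Louvain is greedy and stochastic; we
run `n_runs = 10` seeded restarts (seeds drawn sequentially from one
stream, so a longer stream extends a shorter one and the reported Q is
monotone in `n_runs`) and keep the best-Q partition. Q is always
re-evaluated by direct application of the formula, never taken on
faith from the optimizer; the test suite checks Louvain against an
exhaustive set-partition enumeration on all 142 connected graphs with
≤ 6 nodes plus a seeded sample of 7-node graphs (the graph atlas ends
at 7 nodes, and the partition brute force grows with the Bell
numbers, so the oracle suite stops there).

**Overlap.** Communities of *edges* are found Ahn-style: two edges
sharing node k, (i,k) and (j,k), have similarity
`|n⁺(i) ∩ n⁺(j)| / |n⁺(i) ∪ n⁺(j)|` with `n⁺(x) = {x} ∪ neighbors(x)`;
non-adjacent edge pairs have similarity 0 and can only merge through
chains. Edges are clustered by single linkage and the dendrogram is
cut at the maximum of the partition density D (communities of a single
edge contribute 0). Every node inherits the labels of its incident
edges; the overlap score is the mean membership count per node. The
normalized variant divides by the mean overlap score of 10
degree-preserving random nulls, which calibrates away degree-sequence
effects (an ER graph scores ≈ 1 against its own nulls).

Numerical conventions, chosen for determinism and checked by tests:
edges are ordered lexicographically (mixed-type node labels ordered by
type name, then value); merge ties at equal similarity follow that
edge order; ties between cuts of equal partition density go to the cut
with fewer communities; isolated nodes receive one private singleton
membership so every node belongs to at least one community.

Single-edge communities **count** toward node memberships by default.
This is the main sensitivity knob of the overlap score
(`overlap_score(..., count_single_edge_communities=False)` gives the
variant): at the partition-density optimum many sparse regions resolve
into one- and two-edge communities, and counting them raises overlap
scores substantially in weakly modular regimes. The default follows
the standard link-community convention of treating every cluster of
the edge partition as a community.

## Null models

Degree-preserving double edge swaps, `10·m` attempted swaps by default
(the common rewiring budget for this family of nulls). Swaps creating
self-loops or multi-edges are rejected. With `require_connected` (the
default), a swap may never increase the number of connected
components — checked by post-swap reachability of both rewired pairs —
which reduces to connectivity preservation on connected inputs and is
well-defined on disconnected ones. The latticized null additionally
requires each swap to strictly reduce the total circular ring distance
of the edge set under the sorted node ordering.

## Planted-partition sweep

Equal-module planted-partition graphs over a (p_in, p_out) grid; per
cell, `replicates = 5` networks are scored (segregation, overlap,
overlapping-community count, segregated-structure flag) and averaged.
The reference grids are p_in ∈ [0.7, 1.0] and p_out ∈ [0.01, 0.35] at
0.02 steps over seven (N, M) configurations — (100,5), (200,5),
(300,5), (120,4), (120,6), (120,8), (120,10); tests and the acceptance
script run the (100, 5) configuration at 0.06 steps, which preserves
the phenomenon of interest: the overlap score has an interior maximum
at moderate segregation (≈ 0.27 at these settings), falling off toward
both weakly and strongly segregated regimes. When a draw is
disconnected, its largest component is scored. "Rescaled over the
maximum" normalizations are applied after replicate averaging, per
configuration.

## Topological reinforcement

From a connected ER start (N = 164, mean degree λ = 16, i.e. 10%
density), each step samples ⌊N/2⌋ nodes with degree ∉ {0, N−1}, adds
for each a link to the non-neighbor with the most common neighbors
(scored against the pre-step graph; the batch is applied at once and
duplicate proposals collapse; score ties are broken uniformly from the
seeded stream), then deletes as many uniformly random links as were
actually added, resampling any deletion that would disconnect the
graph (retry budget 100 per deletion). Node count and density are
exactly conserved; evolution runs 60 steps.

Along the trajectory we record segregation, overlap, global efficiency
(mean inverse shortest-path length over ordered pairs, 0 for
disconnected pairs), local efficiency (mean neighbor-subgraph global
efficiency; degree < 2 contributes 0), and the steady-state
activated-node ratio of the linear threshold model (θ = 0.5, 32% seed
nodes, 20 random seed sets per step). Reference ensembles average 50
runs; tests and the acceptance script use 10.

Measured behaviour at these settings: segregation rises monotonically
(≈ 0.21 → 0.37 over 60 steps); the overlap score is 1 for the first
few steps (a random graph forms a single link community), jumps as
modular structure emerges, peaks around step 10–12, and declines as
modules consolidate; the activated ratio peaks within a few steps of
the start and co-locates loosely with the overlap peak; global
efficiency has a shallow interior maximum near step 25–30; local
efficiency increases throughout the 60 steps without an interior
maximum. The tight co-location of *both* routing efficiencies with
the overlap peak is therefore not reproduced under the default
overlap convention at these scales — the corresponding acceptance test
records this faithfully rather than relaxing the check. The
single-edge-community knob shifts the overlap peak and is the first
thing to vary when exploring this discrepancy.

## Linear threshold model

Influence is receiver-normalized: each active neighbor contributes
`1/degree(v)` to node v, so incoming weights sum to 1 (the standard
linear-threshold convention). A node with at least one active neighbor
activates when its summed influence reaches θ; the comparison is `≥ θ`
by default (`strict_threshold` flips it to `>`, which matters at
θ = 0.5 on even-degree nodes). Requiring an active neighbor keeps
degree-0 nodes inactive unless seeded, including at θ = 0. Updates are
synchronous to a fixed point; because activation is permanent and the
rule monotone, the fixed point is order-independent (verified against
an asynchronous random-order oracle).

## Sliding-window flexibility

Windowed Pearson correlation over a nodes × time panel. The window
length in samples is `round(window_s / sampling_s)` — 42 samples for
the canonical 30-s window at 0.72-s sampling, giving 4759 windows on a
4800-sample scan at a one-sample step (41 samples would give 4760; 42
is the value consistent with that window count). Zero-variance cases
within a window get correlation 0 (logged).

Per window, communities are found by weighted Louvain on the positive
correlations (negative weights zeroed; per-window weighted modularity,
γ = 1). Labels are then tracked across consecutive windows by an
optimal one-to-one assignment (Hungarian) maximizing community Jaccard
overlap; communities with no positive-overlap partner get fresh
labels. This tracking step is the central reconstruction decision: a
node's "allegiance change" is only meaningful against matched labels,
and the matcher absorbs arbitrary label permutations (a property
test). A multilayer community model with explicit inter-layer coupling
is a possible alternative and can be swapped in behind the same
interface. Flexibility of a node is the fraction of consecutive-window
transitions at which its matched label changes; the mean over nodes
summarizes the panel.

## Synthetic cohort

Each subject gets:

1. **Structural network** at exactly 10% link density. Modules are
   planted with M = 4 equal modules; the within-module probability
   p_in is drawn uniformly from [0.15, 0.38] and p_out is solved so
   the expected density is the target, then edges are randomly
   trimmed/padded to the exact count. (Dense-module regimes with
   p_in ≥ 0.7 are incompatible with 10% density at these sizes; this
   range spans weak to near-maximal module contrast at that density.)
   The default roster is N = 164 nodes.
2. **Functional panel** (default 50 nodes × 4800 samples at 0.72 s): a
   latent module partition (5 modules) is redrawn at Poisson-many
   switch times, uniformly placed in the scan; node signal = module
   latent (iid standard normal per sample) + Gaussian noise with
   SD 0.816, giving within-module correlation ≈ 0.6, typical of
   sliding-window FC regimes. The expected number of switches is
   `2 + 8 · overlap percentile`, coupling dynamic reconfiguration to
   structural overlap.
3. **Three behavior scores** (pattern-completion-, card-sorting-,
   flanker-like), each `r·z + √(1−r²)·ε` with z the cohort-standardized
   normalized overlap and r = 0.26, so the population overlap–behavior
   correlation equals the planted coupling by construction (scores are
   left in standardized units rather than imitating toolbox scales).

What the generator does **not** emulate: hemodynamics and scanner
noise, realistic degree distributions or spatial embedding of
connectomes, heterogeneous module sizes, and any atlas structure.
Passing recovery tests therefore demonstrates that the pipeline's
estimators are consistent and correctly coupled, not that the effect
sizes would survive real imaging noise.

## Analysis scales

Default study-condition parameters (ER λ = 16 at N = 164, 60 TR steps,
θ = 0.5, 10 nulls, 30-s windows, n = 100 subjects, planted r = 0.26)
are kept everywhere. Where an analysis is replicated many times, the
package's tests and acceptance script run documented reduced scales:
TR ensembles of 10 (reference 50); sweep grids at 0.06 steps; cohort
structural networks of N = 40 at 10% density with panels of T = 1200
samples, window step 40 samples, flexibility on 16 subjects per
cohort; oracle suites on ≤ 7-node graphs. These sizes are the
package's own validation choices and are stated alongside each result.

## Known limitations

- Louvain is a heuristic; optimality is only guaranteed on the small
  oracle fixtures. Different restart counts can change Q in the fourth
  decimal on large graphs.
- Single-linkage link communities chain through weak similarities; on
  ER-like graphs the partition-density optimum is often the single
  giant community (overlap exactly 1), so overlap scores are
  discontinuous at the onset of modular structure.
- The latticized null uses a circular ring cost under the sorted node
  order; other orderings define other lattices.
- Welch's t-test is used for all group contrasts (variances are not
  assumed equal); p-values are reported raw.
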