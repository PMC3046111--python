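# Methods

This note documents the models implemented in `keymir`, their assumptions,
the parameters that matter, the numerical choices, and what the synthetic
benchmark does and does not demonstrate.

## Expression classification

The design assumes one pooled log2 expression value per miRNA per group
(control, disease, disease+drug, drug-only) — replicates are pooled before
hybridization, so no replicate-level statistics are possible and none are
attempted. The two calls are simple thresholds:

* **Dysregulated:** |disease − control| ≥ `dysregulation_threshold`
  (default 0.5 log2 units, boundary inclusive — "at least" semantics).
* **Drug-reversed:** a dysregulated miRNA whose treated value moves from
  the disease value *toward* control (same sign as control − disease) with
  linear fold change `2^|disease_drug − disease|` strictly greater than
  `reversal_fold_threshold` (default 1.5). Mere change away from control
  does not count as reversal. Fold changes are computed on the linear
  scale from the log2 differences.

Between-group similarity over the dysregulated set is the Pearson
correlation of the two deviation-from-control vectors. It is symmetric,
bounded in [−1, 1], undefined for fewer than 3 dysregulated miRNAs or a
zero-variance deviation vector. This is a documented stand-in for an
unspecified published similarity measure; it reproduces the qualitative
use (a between-group similarity heatmap) without claiming to be the
original formula.

## PPI networks and the static score

Networks are built from weighted edge lists (STRING-style). Scores in the
0–999 integer dialect are auto-detected (any score > 1) and rescaled by
1/1000. Edges are kept at confidence ≥ `confidence_threshold` (default
0.7, inclusive); duplicate undirected edges collapse to the maximum
confidence, self-loops are dropped, and only endpoints of retained edges
become nodes. Confidence is used **only** for filtering and later for
clustering weights; degree and neighborhood connectivity are computed on
the unweighted filtered topology, matching the conventions of standard
network-analysis tools.

For a target set T with at least one protein in the network,

    static = mean_deg(T)/mean_deg(V) + mean_nc(T)/mean_nc(V) − offset,

with `nc(v)` the arithmetic mean degree of v's neighbors (0 for an
isolated node, by convention) and means taken arithmetically over target
*nodes*. "Normalization" is ratio-to-network-mean: it is the only reading
under which the conventional offset (3.3) and enhanced cutoff (0.6)
coexist with scores of order 1 — note the all-targets baseline is then
exactly 2 − offset. The offset's provenance is conventional; it is exposed
in the configuration rather than rationalized. Targets absent from the
network are excluded from the means and reported separately; a miRNA with
no in-network target gets an explicit undefined record, which propagates
as "not evaluable" through the enhanced-on-both-networks classification.
The second network is optional; without it the combined flag degrades to
the single-network flag with a logged notice.

Target credibility is summarized as the fraction of target records that
are experimentally validated or predicted with p < `target_p_cutoff`
(default 0.01).

## Mass-action perturbation and the dynamic score

The perturbation model treats every retained PPI edge as a reversible
dimerization `P_i + P_j ⇌ C_ij` with a single global association constant
K (default 1.0, in reciprocal concentration units): no per-edge affinities
are available at proteome scale, so uniform affinity is the least-informed
choice. At equilibrium `complex_ij = K·free_i·free_j` and mass balance
gives the fixed point

    free_i = total_i / (1 + K·Σ_{j∈N(i)} free_j).

**Solver.** Damped fixed-point iteration (damping 0.5) on the free
concentration vector, starting from `free = total` (or warm-starting from
the baseline state for perturbations). Convergence is declared when the
maximum relative mass-balance violation drops below `solver_tol` (default
1e−10); non-convergence after `solver_max_iter` (10 000) raises a
convergence error carrying the residual. The iteration is deterministic —
no randomness anywhere in the solver — and the solution is unique for
nonnegative totals, so the result is independent of damping and node
order to within tolerance.

**Totals.** Gene expression values on the linear scale serve as the
protein-abundance proxy; non-positive or missing values are floored at
1e−6 so every node participates in the equilibrium.

**Perturbation.** The totals of a miRNA's in-network target proteins are
multiplied by a fold factor: 0.5 for an up-regulated miRNA (more miRNA →
less protein) and 2.0 for a down-regulated one; the magnitude is a
modeling choice exposed in configuration and recorded in the output. Each
non-source node's response is `max(f′/f, f/f′) ≥ 1` (1 when both are 0).
Sources are excluded from subgroup counting by default (toggleable), so
the score measures propagation rather than the imposed change. Subgroup
thresholds are interpreted as fold-change cutoffs; the defaults (1.2 and
2.0) give `dynamic = S(2.0)/S(1.2) ∈ [0, 1]`, with 0 when nothing is
perturbed — S is non-increasing in the threshold, so the ratio is always
a fraction.

A useful physical intuition validated by the implementation: a source
only perturbs a neighbor strongly when its free concentration is
comparable to the neighbor's total binding (`K·Δfree_source ≳ 1 +
K·Σ other partners`). A scarce protein, however central, propagates
nothing; a protein that dominates its binding neighborhood pushes its
partners past both thresholds.

## Module discovery and enrichment

Each candidate miRNA's emphasis is sought in the subgraph induced by its
in-network targets (already confidence-filtered). Clustering is a
re-implementation of cohesiveness-based overlapping clustering in the
style of ClusterONE:

* cohesiveness of a vertex set V: `w_in / (w_in + w_bound + p·|V|)` with
  edge weights = confidences and per-vertex penalty p (default 2.0);
* greedy growth from a singleton seed: at each step the single boundary
  addition or member removal with the largest strict cohesiveness
  increase is applied (ties prefer additions, then the lexicographically
  smallest node), until no move improves;
* seeds are taken in decreasing degree order (ties lexicographic) over
  nodes not yet covered; a grown cluster covers its nodes only if it
  passes the size and density filters, so degenerate growths do not
  starve real modules of seeds;
* near-duplicate clusters with overlap score `ω(A,B) = |A∩B|²/(|A||B|) ≥
  0.8` are merged by union; merged clusters below `min_size` (3) or
  weighted internal density < `min_density` (0.5) are discarded;
* output order and the largest-module rule are fully deterministic:
  size, then cohesiveness, then lexicographic members. All tie-breaking
  in the package is lexicographic on identifiers so results are
  bit-stable under input reordering.

Enrichment of a module against each gene set is the hypergeometric
upper-tail probability of the observed overlap (universe = all network
nodes), Benjamini–Hochberg adjusted across sets.

Known limitation: greedy cohesiveness maximization legitimately absorbs a
non-member that has two or more confident edges into a module (the gain
arithmetic favors it), and occasionally an entire dense subnetwork is one
cohesive object that the density filter then rejects wholesale. Recovery
of a planted module is therefore excellent but not surgically exact —
see the benchmark section.

## Synthetic benchmark

The generator emulates the statistical shape of the study inputs at desk
scale; all generators are pure functions of (config, seed).

* **Network:** preferential attachment, 500 nodes, attachment 3 (~1500
  edges) — heavy-tailed degrees like a STRING-derived PPI network but
  small enough that the full suite runs in seconds; confidences uniform
  [0.7, 1]; abundances log-normal (meanlog 2, sdlog 1 on the natural
  scale), heavy-tailed like expression data.
* **Planted modules:** 3 disjoint 8-member sets densified at intra-edge
  probability 0.9 (confidences uniform [0.7, 1]).
* **miRNAs:** 40 total, 12 dysregulated, 7 reversed, 3 key — scaling the
  motivating study's proportions (102 detected / 31 dysregulated / 18
  reversed / 3 prime candidates) by ~0.4.
* **Expression:** control baselines N(8, 1); planted disease effects with
  magnitude uniform [0.9, 1.4] (≥ 2.8 noise-SD beyond the 0.5 call
  threshold, so recovery tests are sharp rather than flaky); reversals of
  at least 0.85 log2 (fold ≥ 1.8 > 1.5, again ≥ 1.9σ margin);
  non-reversed miRNAs move at most 0.2 under drug; i.i.d. N(0, 0.1)
  noise on every value.
* **Targets:** each key miRNA targets one planted module plus the top 15
  hubs plus random fill (25 targets each, like background miRNAs); ~60%
  of records are validated or confidently predicted (40% validated; a
  third of predictions get p < 0.01), mirroring the credibility fraction
  typical of curated-plus-predicted target maps.
* **Planted efficiency:** the key miRNAs' target proteins are reassigned
  dominant abundances (boost of 2.5 on the log scale). Under the
  mass-action model this — not low abundance — is what lets a
  perturbation propagate: a low-abundance source has negligible free
  concentration and moves nothing past the fold thresholds. One
  consequence is that in the synthetic data the dynamic score correlates
  *positively* with mean log2 target abundance; the inverse correlation
  reported on real data reflects abundance–topology structure that this
  generator does not emulate.
* **Gene sets:** one disease set = the planted module members, plus 10
  size-matched uniform decoys.

**What passing tests show.** On this benchmark the classifier recovers
the planted dysregulated/reversed sets with ~99.5% mean per-miRNA
accuracy (100 seeds); the planted key miRNAs are the only candidates that
survive the reversed-and-enhanced filter and land in the ranking's top 3
in every tested seed; the planted modules are recovered from the key
miRNAs' target subnetworks with mean best-Jaccard ≈ 0.97 (per-module
recovery is occasionally 8/9 ≈ 0.89 when a genuinely cohesive hub joins,
and rarely 0 when the whole subnetwork is one dense blob rejected by the
density filter). **What they do not show:** performance on real arrays
(probe-level noise, normalization artifacts), on real PPI networks (false
positives, ascertainment bias toward well-studied proteins), or with real
target predictions (correlated errors); the separation between key and
background miRNAs is planted and sharp, whereas real effect sizes
straddle the thresholds.

## Ranking rule

The published narrative combines three lines of evidence (reversal,
enhanced static regulation on both networks, module disease-enrichment
with dynamic efficiency) without stating a single formula. `keymir`
codifies it as an explicit, testable rule: filter to reversed miRNAs with
enhanced static regulation (both networks when two are given), sort by
disease-set adjusted enrichment p ascending (candidates without a module
sort last), then dynamic score descending, then identifier. This is an
interpretation, marked as such; all stage outputs are written to the
report bundle so any other combination rule can be applied downstream.

## Degenerate inputs and error behavior

Missing group columns, malformed edge or target lines (reported with line
numbers), empty post-filter networks, identifier-space mismatches between
targets and network, and non-positive thresholds all raise typed errors;
the CLI maps input/parameter errors to exit code 2 and solver
non-convergence to exit code 3. Quantities that are undefined on an input
(similarity with < 3 miRNAs, static score with no in-network target,
correlation with < 3 pairs, enrichment of an empty module list) raise or
mark explicitly rather than returning a number.

## Problem sizes

Default test and acceptance problem sizes (500-node networks, 40 miRNAs,
25–100 seeds per recovery estimate) were chosen so the whole suite and
the acceptance script each complete in well under a minute on one core
while keeping every statistical margin (noise SD vs threshold distances,
binomial counts) wide enough that the planted-recovery assertions are
stable across seeds.
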