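# Methods

This note documents the models, numerical choices and limitations behind
`cophylo`, in the order the analysis chain runs.

## Trees and distances

Trees are parsed and written as Newick through dendropy and held in a
plain parent/child structure. A tree whose basal node has two children is
*rooted*; a basal multifurcation marks an *unrooted* tree. Internal-node
labels (including numeric support values) survive round-trips but are
ignored by every computation. Branch lengths are optional nonnegative
reals; patristic distances require them all (the basal node's own length is
irrelevant and ignored).

Multifurcations are accepted on input. Reconciliation and rooting
enumeration require binary trees, so `PhyloTree.resolve_polytomies()`
resolves them deterministically — left-to-right caterpillars of zero-length
edges — and logs a warning. The resolution is arbitrary by construction;
weakly supported nodes have no unique resolution, and a zero-length
caterpillar adds no patristic distance.

Rerooting inserts a degree-2 node on a chosen edge. Edges are addressed by
the leaf set on their child side (stable across copies, unlike node ids).
The split position along the edge defaults to the midpoint and is
configurable; reconciliation is topology-only, so this choice affects only
branch-length outputs. Rerooting preserves the leaf set, total tree length
and all leaf-to-leaf patristic distances; for a binary unrooted tree with
n leaves there are exactly 2n−3 candidate root edges.

## Global fit (Procrustes approach)

1. **PCoA.** Gower double-centering of −½D², symmetric eigendecomposition,
   axes ordered by decreasing eigenvalue. Axes with eigenvalues ≤ 1e−10
   (relative to the leading eigenvalue) are dropped. Patristic matrices are
   tree-additive and in practice embeddable; for non-Euclidean inputs the
   Lingoes correction (add 2c to squared off-diagonal distances) and the
   Cailliez correction (add c to off-diagonal distances, constant from the
   standard 2n×2n companion eigenproblem) are available. Default: no
   correction, negative axes dropped.
2. **Expansion.** One row per link: the host row of the link's host, the
   symbiont row of its symbiont. A host with several symbionts contributes
   several rows. The narrower configuration is zero-padded to equal width,
   never truncated, so no variance of either embedding is discarded.
3. **Superimposition.** The symbiont configuration is fitted onto the host
   configuration by least squares: centering, rotation from the SVD of
   YᵀX with reflection permitted, and scale s = tr Σ / ‖Y꜀‖². Scaling is
   estimated because host and symbiont branch lengths are in different
   substitution-rate units. m² is the residual sum of squares and is
   reported with its per-row (per-link) decomposition. Degenerate case:
   if all symbiont points coincide, the fit collapses onto the host
   centroid (s = 0) and m² is the host configuration's total variance.
4. **Permutation test.** The observed m² is compared with m² values from
   randomised association matrices. Two schemes are exposed because the
   appropriate null depends on how links arise: `full-shuffle` (default)
   redraws the binary association matrix uniformly among matrices with the
   same total number of links; `row-shuffle` permutes the symbiont column
   of the link list, preserving each host's link count (and each
   symbiont's). p = (1 + #{m²ₚₑᵣₘ ≤ m²ₒᵦₛ})/(N+1), always in (0, 1].
   The default N is 100,000 (configurable upward; p-value resolution is
   1/(N+1)). Calibration was verified by simulation: with links drawn from
   the same distribution the full-shuffle null redraws, the test is
   exactly exchangeable and rejects at the nominal rate (measured
   0.040–0.058 at α = 0.05 over 500 replicates, several seeds).
5. **Jackknife.** For link i, each deletion j ≠ i yields the pseudovalue
   n·r_full,i − (n−1)·r₍₋ⱼ₎,i. The estimate is the mean pseudovalue
   clipped at 0; the upper bound adds t₀.₉₅,ₙ₋₁ standard errors of the
   pseudovalue mean (one-sided 95%). Values are keyed by link, so input
   order is irrelevant. With m² = 0 all pseudovalues are 0 and the
   intervals have zero width.

## Event-based reconciliation

The solver maps each symbiont node to a host node. Costs: cospeciation 0,
duplication 1, loss 1, host switch 2 by default ("duplication then host
switching" is priced as the single switch event). Branch lengths are
ignored.

The exact mode is a bottom-up dynamic program. For symbiont node p and
host node e, `C[p][e]` is the cheapest embedding with p's divergence at e
and `IN[p][e]` the cheapest with p at e or anywhere below (each step down
a host edge adds one loss). Internal nodes take the cheapest of:

* **cospeciation** (e internal): children into opposite child subtrees,
  both pairings considered;
* **duplication**: both children at or below e;
* **host switch**: one child at or below e, the other at or below any
  *target* host node that is neither e nor an ancestor of e (the undated
  model: descendants are legal targets). With time zones, target and
  source must share a zone.

No loss is charged above the symbiont root's placement: the total is
min over e of `C[root][e]`. Complexity O(|S|·|H|²); instances with
hundreds of leaves solve in well under a second.

**Tie-breaking.** The optimal cost is unique; the optimal mapping often is
not. Traceback prefers cospeciation > duplication > host-switch, then the
left-most (preorder-first) host position, so repeated runs return the same
reconciliation. Only the cost feeds downstream ranking.

**Time zones** partition host nodes into ordered eras 1..K via a label→zone
table; unlabelled nodes inherit their nearest labelled ancestor's zone
(root defaults to 1), and assignments must be monotone along ancestry.
Symbiont divergences are restricted to hosts with zone ≥ a configurable
minimum. Constraints can only raise the optimum; infeasible configurations
raise an explicit error rather than returning a sentinel cost.

**Genetic mode.** A seeded GA over internal-node host assignments
(tournament selection, uniform crossover, 20% mutation, elitism; defaults
500 generations × population 30) exists to mirror metaheuristic
reconciliation tools. It is labelled heuristic (`Reconciliation.exact =
False`), can never report less than the DP optimum, and is not used by any
other stage.

**Composite host trees.** `build_composite_host_tree` grafts a second host
clade (e.g. a hypothesised arthropod history) as sister to a named node,
with a configurable graft edge length (default 1.0) so patristic
computations stay defined; reconciliation ignores those lengths.

## Root scan

Candidates are all edges of the unrooted symbiont tree, or named clades
given as leaf sets (resolved to the subtending edge; non-monophyletic sets
are an error naming the offending leaves). Each candidate is rerooted and
solved exactly under one shared regime/zone configuration; results are
sorted by cost with a stable name tie-break. Ties are reported as a
co-optimal set and never broken: when cost differences between rootings
are weak, hiding ties would overstate resolution.

## Simulator

Symbiont lineages evolve tipward along the host tree; host node times come
from the host's branch lengths (host trees from `simulate_host_tree` have
uniformly-split Yule-type topologies and exponential edge lengths).

* At each **host speciation** a lineage cospeciates with probability
  `p_cospeciation` or misses the speciation and follows one uniformly
  chosen child (a loss) with probability `p_loss`; the two must sum to 1.
* Along each **host edge** a lineage undergoes at most one duplication
  (Bernoulli `p_duplication`, time uniform on the edge); daughters do not
  re-duplicate on the same edge, which keeps per-edge growth bounded and
  the event count finite.
* A duplicated daughter **switches** with probability `p_switch` to a host
  edge chosen uniformly among those crossing the duplication time
  (switches only occur at duplications). If no other edge is
  contemporaneous the daughter stays and the event is a plain duplication.

Defaults (0.85 / 0.15 / 0.10 / 0.30) give cospeciation-dominated
tanglegrams with occasional losses, duplications and switches — the regime
in which mixed vertical/horizontal symbiont histories are typically
discussed. Extinct host lineages are not simulated, and lineages never die
(a loss prunes descent on one side only), so every simulated symbiont leaf
maps to an extant host leaf. Every event is logged with lineage ids;
`replay_event_log` rebuilds the symbiont tree from the log alone, and the
recorded counts price the true history, which upper-bounds the solver's
optimum (equality whenever `p_switch = p_loss = 0`, since
duplication/loss-only histories are themselves optimal embeddings).

What the simulator does **not** emulate: sequence evolution and
phylogenetic estimation error (trees are known exactly, so test power on
simulated data is an upper bound on real-data power), host extinction,
branch-length-dependent event rates, and failure-to-diverge events.

## Infection-status fixture

One row per filarial species: clade (ONC1–ONC5), status, newly-examined
and new-strain flags, study-sample membership, evidence source, supergroup
when known, and a citation tag. Rows whose tag names a table or figure
carry statuses stated in the source text; rows tagged `reconstructed` are
synthetic stand-ins for the prior-report roster (published only in a
supplement) chosen so the aggregate counts hold exactly: 45 study species
(26 positive → 58%), 16 newly screened (7 new strains, 9 negative),
ONC3–ONC5 study subset 25/35 → 71%, combined 45/85 → 52.9%. Percentages
are species-level (specimen duplicates collapse; conflicting duplicate
statuses are an error) and rounded half-up to the printed precision.

## Problem sizes and numerical choices

* Exhaustive-enumeration cross-checks run on instances with ≤ 6 host and
  ≤ 6 symbiont leaves (200 random instances), where enumeration over all
  internal-node placements is tractable; the DP is size-independent.
* Null calibration uses 500 replicates of 10+10-leaf tanglegrams at 199
  permutations; root-scan recovery uses 100 replicates of 12-leaf hosts
  with ≥ 10 surviving symbiont lineages.
* Floating-point cost comparisons use absolute tolerance 1e−9; PCoA axis
  retention uses relative tolerance 1e−10; Procrustes identity checks hold
  to 1e−9.
* All randomness flows through `numpy.random.default_rng` seeded
  explicitly; every stochastic stage is bit-reproducible given its seed,
  and the pipeline report is byte-identical across reruns.
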