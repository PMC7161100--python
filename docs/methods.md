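# Methods

## Objects and conventions

All trees are unrooted and leaf-labelled; rooted newick input is
accepted and its degree-2 root suppressed on parse, since essentially
all on-disk trees are written rooted. Internal nodes of degree 2 are
never allowed to persist, so edges correspond one-to-one with
bipartitions. Branch lengths and internal-node labels are carried
through I/O but are inert: every topological operation ignores them,
and edges created by subdivision or joining carry no length (the merge
is purely topological; assigning lengths to new edges would be an
estimation problem this package does not attempt). When a degree-2
node is suppressed its two incident lengths are summed.

A bipartition is stored orientation-free, canonicalized so that the
block containing the lexicographically smallest taxon of its reference
leafset is `side_a`; equality and hashing act on the frozen blocks,
which also means splits over different leafsets never collide. Only
nontrivial splits (both sides ≥ 2) enter `C(t)` by default: trivial
splits are shared by all trees on a leafset and can never affect an FN
or RF count, and the standard `2N − 6` normalization counts nontrivial
splits only.

## Distances

`fn_distance(a, b) = |C(b) \ C(a)|` is directional; the merge
objective is `fn_distance(supertree, guide)`, i.e. the number of guide
splits the merger fails to realize. `rf_distance` is the symmetric
difference and always equals the sum of the two FN directions. For a
pair of binary trees the two directions coincide and FN = RF/2; the
package keeps the per-direction definition throughout and the test
suite records the FN = RF/2 identity explicitly rather than conflating
the two metrics. Non-binary trees are accepted by all metrics — that
is precisely why FN rather than RF is the optimization target, since a
polytomy withholds splits without asserting wrong ones.

## The merge algorithm

Inputs are validated first: constraint leafsets must be pairwise
disjoint and their union must equal the guide leafset (the error
message lists missing/extra taxa). Constraint trees may be non-binary
and may have 1 or 2 leaves; single-node components attach at their
vertex since they have no edge to subdivide.

Guide edges are classified by how many constraint sets have leaves on
both sides: 0 (bridge), 1 (lies within that set), ≥ 2 (violates
convexity). The collapse phase removes, in one pass over a single
edge-table, (a) every internal edge whose split restricted to some
constraint leafset is a nontrivial split absent from that constraint
tree, then (b) every remaining convexity-violating edge; the two
counts are reported separately, and an edge failing both tests is
counted under (a), matching the order in which the phases are defined.
After collapse, every surviving within-edge's restricted split is
present in its constraint tree by construction.

The recursive rejoin keeps the classical structure: if the current
component's leafset equals one constraint's leafset, return that
constraint tree; otherwise pick a splitting edge — an existing bridge,
or, when none exists, a refinement edge manufactured at a junction
node where edges of two different constraint sets meet, pulling all
edges of one chosen set onto a new node. Delete the splitting edge,
record one flanking edge on each side (by its split within that side's
leafset — the split, not the edge identity, is the stable key across
recursion), recurse on both sides, locate in each returned supertree
the edge inducing the recorded split via a hash table of splits, and
join by subdividing the two located edges and adding an edge between
the subdivision points. The located split is guaranteed to exist; its
absence would indicate a bug and raises an invariant error rather than
attaching anywhere else (the property suite and the brute-force oracle
never trigger it).

Degenerate cases handled explicitly: a junction refinement always
pulls ≥ 2 edges (an edge lying within a set at a node forces a second
such edge at that node), so refinement never creates a degree-2 node
while bridges are absent; a bridge endpoint that is a leaf yields a
single-node side attached at its vertex; endpoints left at degree 2 by
the split are suppressed before recursing.

### Tie-breaking

The theory guarantees optimality for *any* admissible choice of
splitting edge and flanking edges, so ties are broken purely for
reproducibility: among bridges, the one whose far-side leafset has the
smallest taxon (then fewest leaves); among junctions, the one whose
pullable constraint set has the smallest taxon (then the stable node
order); among flanking edges, smallest far-side taxon. Output newick
is therefore byte-identical across runs. A seeded random-tie mode
(`random_ties_seed=`) replaces each deterministic choice with a draw
from one `random.Random`, reproducible per seed; it can only change
which equally-optimal supertree is returned, never the FN value. FN
ties between distinct optimal supertrees are not broken by any
secondary criterion — the deterministic policy's pick is arbitrary but
documented.

### Performance

All leafset arithmetic on the hot paths uses integer bitmasks (one bit
per taxon, assigned in lexicographic order so the lowest set bit is
the smallest taxon), making split identity tests word operations.
Constraint split tables and attachment lookups go through hash tables
whose insertions/lookups are counted in `MergeResult.hash_ops`; with
subset bound B fixed, the count grows as roughly N·k ≈ N²/B, and the
measured log-log slope from N = 250 to N = 2000 is ≈ 1.5. A
2000-taxon, 27-component merge takes ~2 s single-threaded.

## Centroid decomposition

`centroid_edge` minimizes the absolute difference of leaf counts over
all edges; the minimizer is often non-unique, and ties are broken
toward the edge whose smaller side contains the smallest taxon (then
smaller side size, then lexicographic side content — a total order, so
the decomposition is deterministic). `centroid_decomposition` cuts
recursively until every component has ≤ B leaves; B defaults to 120 in
the CLI, the bound conventionally used with subset methods that
saturate around a hundred taxa. Degree-2 nodes created by a cut are
suppressed before recursing, so intermediate trees stay valid.

## Brute-force oracle

`enumerate_unblended` realizes the entire unblended search space on
small inputs: components are inserted one at a time in **every
insertion order**, each insertion choosing any edge (or sole vertex)
of the growing merged tree and any edge of the incoming component,
with final trees deduplicated on their bipartition sets. Every
unblended merger is reachable this way: its connecting edges form a
tree over the components, some component is incident to exactly one
connecting edge, and deleting it leaves a smaller unblended merger —
induction gives a rebuilding order. Fixing a single insertion order is
*not* sufficient (a later component may need to land between two
earlier ones, e.g. two singletons attaching to different edges of a
third tree), which the optimality tests would expose as the merge
"beating" the oracle. Sites on previously added connecting edges are
included, covering wirings where connecting edges meet at new degree-3
points. A candidate-count bound (default cap 10⁶) aborts enumeration
before a combinatorial blowup; the oracle is a test instrument, not a
user-facing solver. The equivalence of the recursive rejoin with the
collapse-separate-refine restatement of the algorithm is checked
through this oracle rather than by a second implementation.

## Synthetic instances

`make_instance(n, B, guide_error_moves, seed)` emulates the pipeline's
input shape: a uniformly random unrooted binary true tree on `n` taxa
(sequential random leaf attachment), constraints = its induced
subtrees under the centroid decomposition with bound `B` (so the
constraints are correct by construction), and a guide obtained by
applying `guide_error_moves` random NNI moves to the truth. NNI was
chosen over SPR because each move changes exactly one bipartition,
giving the clean bound RF ≤ 2·moves and a controllable error dial.
All randomness flows through one seeded generator per call.

What this does *not* emulate: correlated estimation error (real guide
trees estimated from few loci err preferentially on short branches),
gene-tree discordance under the coalescent, alignment error, and
constraint trees that are themselves wrong. Passing tests therefore
demonstrate the combinatorial guarantees (optimality, compatibility,
scaling) under idealized error, not field accuracy on estimated
inputs. One soft check mirrors the qualitative expectation that merge
quality degrades as the guide degrades: the median normalized RF error
over 20 seeds is rank-correlated (ρ ≥ 0.7) with the NNI move count
across levels {0, 1, 4, 16, 64} at n = 48, B = 12 — a trend assertion,
not per-instance monotonicity, since a single unlucky seed can invert
neighbouring levels.

## Problem sizes used by the checks

Optimality vs. brute force: 200+ seeded instances, k = 2 with
constraint trees of ≤ 6 leaves and k = 3 with ≤ 4 leaves — the largest
sizes at which exhaustive enumeration stays instantaneous per
instance. Identity recovery: n up to 128 across B ∈ {1, …, 120}.
Scaling: n ∈ {250, 500, 1000, 2000} at B = 120 with n/20 NNI moves of
guide error. The full test suite runs in ~20 s; the acceptance script
in ~12 s.

## Known limitations

* Blended merging (needed to make the caterpillar example's guide
  reachable) is out of scope; the unrestricted optimization problem is
  NP-hard.
* No branch lengths or support values are estimated for added edges.
* The oracle's insertion-order enumeration is super-exponential in k
  and is intentionally capped; it exists to certify small instances.
* `parse_newick` accepts one tree per string; multi-tree files are
  split on `;` by `parse_newick_file`, which does not support nexus.
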