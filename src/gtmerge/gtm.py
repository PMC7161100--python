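"""Guide-tree merging of leaf-disjoint constraint trees.

Given a guide tree on the full taxon set and constraint trees on
pairwise-disjoint taxon subsets covering it, :func:`gtm` builds the
compatibility supertree obtainable by connecting the constraint trees
with new edges (an *unblended* merger) that preserves as many guide
bipartitions as possible — equivalently, minimizes the false-negative
bipartition distance to the guide.  The procedure:

1. collapse every guide edge whose bipartition, restricted to some
   constraint leafset, is a nontrivial split absent from that
   constraint tree;
2. collapse every guide edge spanned by two or more constraint sets
   (a convexity violation: constraint sets must occupy connected
   regions of the guide);
3. recursively split the collapsed guide at bridge edges (edges spanned
   by no constraint set), or at refinements of junctions where two
   constraint sets meet, and rejoin the constraint trees across each
   split by subdividing the edges that induce the same local
   bipartitions the guide had next to the split.

The hot paths run on integer bitmask leafsets (one bit per taxon), so
split identity tests are single machine-word comparisons and the whole
merge is near-quadratic in the taxon count.  Lookups into hashed
bipartition tables are counted in ``MergeResult.hash_ops``, which is
what the scaling benchmark measures.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence, Union

from . import metrics
from .errors import InvariantError, ValidationError
from .trees import (
    Bipartition,
    Edge,
    EdgeOrVertex,
    Tree,
    bipartitions,
    collapse_edges,
    leafsets_below,
    split_on_edge,
    subdivide_and_join,
    _preorder,
)


class EdgeKind(Enum):
    BRIDGE = "bridge"
    WITHIN = "within"
    VIOLATES_CONVEXITY = "violates_convexity"


@dataclass(frozen=True)
class EdgeClass:
    """Classification of a guide edge by how many constraint sets span it.

    A constraint set *spans* an edge if it has leaves on both sides.
    Zero spanning sets: BRIDGE (the edge separates constraint sets).
    One: WITHIN that set (``constraint_index`` is defined).  Two or
    more: VIOLATES_CONVEXITY.
    """

    kind: EdgeKind
    constraint_index: Optional[int] = None


@dataclass
class AttachmentDecision:
    """One rejoin step: which components were connected and at which splits."""

    component_a: frozenset[str]
    component_b: frozenset[str]
    split_a: Optional[Bipartition]  # None for a single-taxon component
    split_b: Optional[Bipartition]


@dataclass
class MergeResult:
    supertree: Tree
    fn_to_guide: int
    collapsed_constraint_violations: int
    collapsed_convexity_violations: int
    attachment_log: list[AttachmentDecision] = field(default_factory=list)
    hash_ops: int = 0


# -- input validation & public edge-level operations ---------------------


def validate_inputs(guide: Tree, constraints: Sequence[Tree]) -> dict[str, int]:
    """Check disjointness/coverage; return the taxon -> constraint-index map."""
    if len(constraints) < 1:
        raise ValidationError("need at least one constraint tree")
    taxon_map: dict[str, int] = {}
    for i, c in enumerate(constraints):
        for name in c.leafset():
            if name in taxon_map:
                raise ValidationError(
                    f"taxon {name!r} appears in constraint trees "
                    f"{taxon_map[name]} and {i}"
                )
            taxon_map[name] = i
    guide_taxa = guide.leafset()
    missing = guide_taxa - taxon_map.keys()
    extra = taxon_map.keys() - guide_taxa
    if missing or extra:
        raise ValidationError(
            "constraint leafsets must partition the guide leafset; "
            f"missing from constraints: {sorted(missing)[:10]!r}, "
            f"not in guide: {sorted(extra)[:10]!r}"
        )
    return taxon_map


def classify_edge(guide: Tree, edge: Edge, taxon_map: dict[str, int]) -> EdgeClass:
    """Classify one guide edge as bridge / within / convexity-violating."""
    u, v = edge
    if not guide.has_edge(u, v):
        raise ValidationError(f"({u}, {v}) is not an edge of the guide")
    root = u if not guide.is_leaf(u) else v
    below, parent, _ = leafsets_below(guide, root)
    child = v if parent.get(v) == u else u
    side = below[child]
    other = guide.leafset() - side
    spanning = {taxon_map[x] for x in side} & {taxon_map[x] for x in other}
    if not spanning:
        return EdgeClass(EdgeKind.BRIDGE)
    if len(spanning) == 1:
        return EdgeClass(EdgeKind.WITHIN, next(iter(spanning)))
    return EdgeClass(EdgeKind.VIOLATES_CONVEXITY)


def violates_constraint(pi: Bipartition, t: Tree) -> bool:
    """Does the split ``pi`` contradict constraint tree ``t``?

    ``pi`` violates ``t`` when its restriction to ``L(t)`` is a
    nontrivial split that ``t`` does not contain.  Trivial restrictions
    never violate (every tree on the leafset induces them).
    """
    lt = t.leafset()
    if not lt <= pi.leafset:
        raise ValidationError("constraint leafset not contained in the split's leafset")
    r = pi.restrict(lt)
    if r.is_trivial():
        return False
    return r not in bipartitions(t)


def find_attachment_edge(supertree: Tree, target: Bipartition) -> EdgeOrVertex:
    """Locate the edge of ``supertree`` inducing ``target``.

    For a single-leaf tree the sole vertex is returned.  Absence of the
    target split is an internal-invariant failure (the merge procedure
    only ever looks up splits the theory guarantees to exist), so it
    raises :class:`InvariantError` rather than returning a fallback.
    """
    labels = supertree.leafset()
    if target.leafset != labels:
        raise ValidationError("target bipartition is not over the tree's leafset")
    if len(labels) == 1:
        return next(iter(supertree.nodes))
    root = supertree.node_for_taxon(min(labels))
    below, parent, order = leafsets_below(supertree, root)
    for u in order:
        if parent[u] is None:
            continue
        if below[u] == target.side_a or below[u] == target.side_b:
            return (u, parent[u])
    raise InvariantError(
        f"no edge induces the requested bipartition {target!r}", bipartition=target
    )


# -- the merger ----------------------------------------------------------


def _lowbit_index(m: int) -> int:
    return (m & -m).bit_length() - 1


class _Merger:
    """Bitmask-based implementation shared by the public entry points.

    Taxa are numbered in lexicographic order, so the lowest set bit of
    any leafset mask identifies its smallest taxon — which is what the
    deterministic tie-breaks key on.
    """

    def __init__(
        self,
        guide: Tree,
        constraints: Sequence[Tree],
        rng: Optional[random.Random] = None,
    ):
        self.guide = guide
        self.constraints = list(constraints)
        self.taxon_map = validate_inputs(guide, constraints)
        self.taxa = sorted(guide.leafset())
        self.bit = {name: 1 << i for i, name in enumerate(self.taxa)}
        self.k = len(self.constraints)
        self.cmask = []
        for c in self.constraints:
            m = 0
            for name in c.leafset():
                m |= self.bit[name]
            self.cmask.append(m)
        self.clow = [m & -m for m in self.cmask]
        self.rng = rng
        self.hash_ops = 0
        self.attachment_log: list[AttachmentDecision] = []
        # hashed split tables of each constraint tree, canonicalized to
        # the side holding the constraint's smallest taxon
        self.c_splits: list[set[int]] = []
        for i, c in enumerate(self.constraints):
            table: set[int] = set()
            for bp in bipartitions(c):
                m = 0
                for name in bp.side_a:
                    m |= self.bit[name]
                if not m & self.clow[i]:
                    m = self.cmask[i] ^ m
                table.add(m)
                self.hash_ops += 1
            self.c_splits.append(table)

    # -- mask helpers --------------------------------------------------

    def _names(self, mask: int) -> frozenset[str]:
        out = []
        while mask:
            low = mask & -mask
            out.append(self.taxa[low.bit_length() - 1])
            mask ^= low
        return frozenset(out)

    def _mask_of(self, t: Tree) -> int:
        m = 0
        for name in t.leafset():
            m |= self.bit[name]
        return m

    def _below_masks(self, t: Tree):
        root = t.node_for_taxon(min(t.leafset()))
        order, parent = _preorder(t, root)
        below: dict[int, int] = {}
        for u in reversed(order):
            m = self.bit[t.leaf_label[u]] if t.is_leaf(u) else 0
            for w in t._adj[u]:
                if w != parent[u]:
                    m |= below[w]
            below[u] = m
        return below, parent, order

    # -- phase 1+2: collapse -------------------------------------------

    def collapse(self) -> tuple[Tree, int, int]:
        work = self.guide.copy()
        below, parent, order = self._below_masks(work)
        to_collapse: list[Edge] = []
        n_constraint = n_convexity = 0
        for u in order:
            p = parent[u]
            if p is None or work.is_leaf(u) or work.is_leaf(p):
                continue
            m = below[u]
            spanning = 0
            violates = False
            for i in range(self.k):
                cm = self.cmask[i]
                r = m & cm
                if r and r != cm:
                    spanning += 1
                    comp = cm ^ r
                    if r & (r - 1) and comp & (comp - 1):  # both sides >= 2
                        canon = r if r & self.clow[i] else comp
                        self.hash_ops += 1
                        if canon not in self.c_splits[i]:
                            violates = True
            if violates:
                n_constraint += 1
                to_collapse.append((u, p))
            elif spanning >= 2:
                n_convexity += 1
                to_collapse.append((u, p))
        return collapse_edges(work, to_collapse), n_constraint, n_convexity

    # -- phase 3: recursive rejoin -------------------------------------

    def rejoin(self, t: Tree) -> Tree:
        mask_t = self._mask_of(t)
        present = [i for i in range(self.k) if self.cmask[i] & mask_t]
        if len(present) == 1:
            i = present[0]
            if self.cmask[i] != mask_t:
                raise InvariantError(
                    "recursion component splits a constraint set"
                )
            return self.constraints[i].copy()

        below, parent, order = self._below_masks(t)

        def edge_label(child: int) -> Optional[int]:
            """Constraint index the edge (child, parent) lies within, or
            None for a bridge.  Post-collapse, at most one set spans it."""
            m = below[child]
            for i in present:
                cm = self.cmask[i]
                r = m & cm
                if r and r != cm:
                    return i
            return None

        labels = {u: edge_label(u) for u in order if parent[u] is not None}
        bridges = [u for u, lab in labels.items() if lab is None]

        if bridges:
            if self.rng is not None:
                child = self.rng.choice(bridges)
            else:
                child = min(
                    bridges,
                    key=lambda u: (_lowbit_index(below[u]), below[u].bit_count()),
                )
            u1, u2 = parent[child], child
            mask_s2 = below[child]
            origin1 = origin2 = None  # plain endpoints
        else:
            # no bridge: find a junction where two constraint sets meet
            # and refine it to manufacture one
            candidates = []
            for v in order:
                if t.is_leaf(v):
                    continue
                incident = set()
                for w in t._adj[v]:
                    child = w if parent.get(w) == v else v
                    incident.add(labels[child])
                if len(incident) >= 2:
                    candidates.append((v, incident))
            if not candidates:
                raise InvariantError("no bridge edge and no junction of constraint sets")
            if self.rng is not None:
                v, incident = self.rng.choice(candidates)
                pull = self.rng.choice(sorted(incident, key=lambda i: self.clow[i]))
            else:
                v, incident = min(
                    candidates,
                    key=lambda cv: (min(self.clow[i] for i in cv[1]), cv[0]),
                )
                pull = min(incident, key=lambda i: self.clow[i])
            v2 = t.new_node()
            mask_s2 = 0
            for w in list(t._adj[v]):
                child = w if parent.get(w) == v else v
                if labels[child] != pull:
                    continue
                far = below[w] if parent.get(w) == v else mask_t ^ below[v]
                mask_s2 |= far
                length = t.edge_length(v, w)
                t.remove_edge(v, w)
                t.add_edge(v2, w, length)
            t.add_edge(v, v2)
            u1, u2 = v, v2
            origin1 = origin2 = v  # below/parent maps still refer to v

        mask_s1 = mask_t ^ mask_s2

        spec1 = self._flank(t, u1, u2, origin1, below, parent, mask_t)
        spec2 = self._flank(t, u2, u1, origin2, below, parent, mask_t)

        s1, s2 = split_on_edge(t, (u1, u2))
        # split_on_edge returns (side of u1, side of u2)
        s1p = self.rejoin(s1)
        s2p = self.rejoin(s2)

        site1 = self._locate(s1p, spec1, mask_s1)
        site2 = self._locate(s2p, spec2, mask_s2)
        merged = subdivide_and_join(s1p, site1, s2p, site2)

        self.attachment_log.append(
            AttachmentDecision(
                component_a=self._names(mask_s1),
                component_b=self._names(mask_s2),
                split_a=self._split_of(spec1, mask_s1),
                split_b=self._split_of(spec2, mask_s2),
            )
        )
        return merged

    def _flank(self, t, u, other, origin, below, parent, mask_t):
        """Choose the neighbour edge of the splitting edge at endpoint
        ``u`` and return its split (as the far-side mask) within u's
        component, or ``None`` when u's side is a single node."""
        if origin is None:
            origin = u
        cand = []
        for w in t._adj[u]:
            if w == other:
                continue
            if parent.get(w) in (origin, u):
                far = below[w]
            else:
                far = mask_t ^ below[origin]
            cand.append(far)
        if not cand:
            return None
        if self.rng is not None:
            return self.rng.choice(cand)
        return min(cand, key=lambda m: (_lowbit_index(m), m.bit_count()))

    def _split_of(self, spec, mask_s) -> Optional[Bipartition]:
        if spec is None:
            return None
        return Bipartition(self._names(spec), self._names(mask_s ^ spec))

    def _locate(self, tree: Tree, spec: Optional[int], mask_s: int) -> EdgeOrVertex:
        """Find the attachment site in a rejoined component: the edge
        inducing the recorded split, or the sole vertex."""
        if spec is None:
            return next(iter(tree.nodes))
        below, parent, order = self._below_masks(tree)
        index: dict[int, Edge] = {}
        for u in order:
            if parent[u] is None:
                continue
            index[below[u]] = (u, parent[u])
            self.hash_ops += 1
        self.hash_ops += 1
        edge = index.get(spec)
        if edge is None:
            edge = index.get(mask_s ^ spec)
        if edge is None:
            raise InvariantError(
                "attachment split not present in rejoined component",
                bipartition=self._split_of(spec, mask_s),
            )
        return edge

    # -- driver --------------------------------------------------------

    def run(self) -> MergeResult:
        collapsed, n_con, n_cvx = self.collapse()
        supertree = self.rejoin(collapsed)
        fn = metrics.fn_distance(supertree, self.guide)
        return MergeResult(
            supertree=supertree,
            fn_to_guide=fn,
            collapsed_constraint_violations=n_con,
            collapsed_convexity_violations=n_cvx,
            attachment_log=self.attachment_log,
            hash_ops=self.hash_ops,
        )


# -- public entry points -------------------------------------------------


def collapse_phase(guide: Tree, constraints: Sequence[Tree]) -> Tree:
    """Collapse constraint-violating and convexity-violating guide edges.

    Afterwards every remaining internal edge is either a bridge or lies
    within a single constraint set, and every within-edge's restricted
    split is present in its constraint tree.
    """
    return _Merger(guide, constraints).collapse()[0]


def rejoin(t: Tree, constraints: Sequence[Tree], taxon_map: Optional[dict] = None) -> Tree:
    """Rejoin constraint trees across a post-collapse tree ``t``.

    ``t`` must carry the union of a subset of the constraint leafsets
    and contain no convexity- or constraint-violating edges.
    ``taxon_map`` is accepted for symmetry with :func:`validate_inputs`
    but is recomputed internally.
    """
    relevant = [c for c in constraints if c.leafset() & t.leafset()]
    merger = _Merger(t, relevant)
    return merger.rejoin(t.copy())


def gtm(
    guide: Tree,
    constraints: Sequence[Tree],
    random_ties_seed: Optional[int] = None,
) -> MergeResult:
    """Merge leaf-disjoint constraint trees guided by ``guide``.

    Returns the unblended compatibility supertree minimizing the FN
    distance to the guide.  Tie choices the theory leaves free (which
    bridge to split first, which neighbour edge flanks a split) are
    resolved deterministically by smallest-taxon keys; pass
    ``random_ties_seed`` to resolve them with a seeded RNG instead —
    any choice yields an optimal merger, so only the realized topology
    among equally good ones can differ.
    """
    rng = random.Random(random_ties_seed) if random_ties_seed is not None else None
    return _Merger(guide, constraints, rng=rng).run()
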