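"""Brute-force enumeration of unblended compatibility supertrees.

The merge algorithm claims optimality over all supertrees formed by
connecting the constraint trees with new edges.  This module realizes
that solution space exhaustively — every way of wiring the components
together, every choice of attachment edge — so the claim can be
checked exactly on small instances.  It is a test oracle: deliberately
simple, quadratic-hearted, and capped so a misconfigured call cannot
blow up a test run.
"""

from __future__ import annotations

import math
from typing import Iterator, Optional, Sequence

from .errors import ResourceLimitError, ValidationError
from .trees import Tree, bipartitions, restrict, subdivide_and_join


def is_compatibility_supertree(t: Tree, constraints: Sequence[Tree]) -> bool:
    """True iff ``t`` restricted to each constraint leafset equals that tree.

    Equality is topological: identical bipartition sets over the
    constraint's leafset.
    """
    union: set[str] = set()
    for c in constraints:
        union |= c.leafset()
    if t.leafset() != union:
        return False
    for c in constraints:
        if bipartitions(restrict(t, c.leafset())) != bipartitions(c):
            return False
    return True


def _sites(t: Tree):
    edges = t.edges()
    if edges:
        return edges
    return [next(iter(t.nodes))]  # single-node component: attach at the vertex


def enumerate_unblended(
    constraints: Sequence[Tree], site_cap: int = 10**6
) -> Iterator[Tree]:
    """Yield every distinct unblended merger of the constraint trees.

    Components are attached one at a time, in every possible insertion
    order; each attachment chooses a site (an edge to subdivide, or
    the sole vertex) in the growing merged tree and one in the
    incoming component.  Every unblended merger is reachable this way:
    its connecting edges form a tree over the components, that tree
    has a component incident to only one connecting edge, and removing
    that component yields a smaller unblended merger — so by induction
    some insertion order rebuilds it.  Sites on previously added
    connecting edges are included, which also covers wirings where
    connecting edges meet at new degree-3 points.  Duplicates (same
    bipartition set) are suppressed.

    Raises :class:`ResourceLimitError` if the candidate count bound
    exceeds ``site_cap``.
    """
    k = len(constraints)
    if k < 2:
        raise ValidationError("enumeration needs at least 2 constraint trees")
    seen_taxa: set[str] = set()
    for c in constraints:
        if seen_taxa & c.leafset():
            raise ValidationError("constraint leafsets overlap")
        seen_taxa |= c.leafset()

    edge_counts = sorted((max(1, len(c.edges())) for c in constraints), reverse=True)
    bound = math.factorial(k)
    merged_edges = edge_counts[0]
    for e in edge_counts[1:]:
        bound *= merged_edges * e
        # joining subdivides up to two edges (+1 each) and adds the bridge
        merged_edges += e + 3
        if bound > site_cap:
            raise ResourceLimitError(
                f"attachment-site bound {bound} exceeds cap {site_cap}"
            )

    seen: set[frozenset] = set()

    def grow(merged: Tree, remaining: tuple[int, ...]) -> Iterator[Tree]:
        if not remaining:
            key = frozenset(bipartitions(merged))
            if key not in seen:
                seen.add(key)
                yield merged
            return
        for pos, j in enumerate(remaining):
            nxt = constraints[j]
            rest = remaining[:pos] + remaining[pos + 1:]
            for s1 in _sites(merged):
                for s2 in _sites(nxt):
                    yield from grow(subdivide_and_join(merged, s1, nxt, s2), rest)

    for first in range(k):
        rest = tuple(j for j in range(k) if j != first)
        yield from grow(constraints[first].copy(), rest)


def best_unblended(
    constraints: Sequence[Tree],
    guide: Tree,
    site_cap: int = 10**6,
) -> tuple[Tree, int]:
    """Exhaustively find a merger minimizing the FN distance to the guide.

    Returns ``(tree, fn)`` where ``fn`` is the number of guide
    bipartitions the best merger still misses.  With a single
    constraint tree the answer is that tree itself.
    """
    union: set[str] = set()
    for c in constraints:
        union |= c.leafset()
    if guide.leafset() != union:
        raise ValidationError("guide leafset differs from the union of constraints")
    guide_splits = bipartitions(guide)
    if len(constraints) == 1:
        only = constraints[0].copy()
        return only, len(guide_splits - bipartitions(only))
    best: Optional[Tree] = None
    best_fn: Optional[int] = None
    for cand in enumerate_unblended(constraints, site_cap=site_cap):
        fn = len(guide_splits - bipartitions(cand))
        if best_fn is None or fn < best_fn:
            best, best_fn = cand, fn
    assert best is not None and best_fn is not None
    return best, best_fn
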