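"""Centroid edge decomposition of a tree's leafset into bounded subsets.

This is the dataset-splitting stage of a divide-and-conquer pipeline:
a starting tree is cut at centroid edges — edges whose removal splits
the leaves as evenly as possible — until every component holds at most
``B`` taxa.  The resulting subsets are "local" in the starting tree,
which is what makes the later merge step well-posed.  Subset trees are
estimated by external methods and are not computed here.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError
from .trees import Edge, Tree, leafsets_below, split_on_edge


@dataclass
class Decomposition:
    """A partition of a tree's leafset into disjoint subsets of size <= B."""

    subsets: list[frozenset[str]]
    max_size: int

    def __post_init__(self):
        for s in self.subsets:
            if len(s) > self.max_size:
                raise ValidationError(
                    f"subset of size {len(s)} exceeds bound {self.max_size}"
                )


def centroid_edge(t: Tree) -> Edge:
    """An edge whose removal minimizes the leaf-count imbalance.

    The centroid edge need not be unique; ties are broken toward the
    candidate whose smaller side contains the lexicographically
    smallest taxon (then the smaller side's size, then its full sorted
    content), which keeps the decomposition deterministic.
    """
    labels = t.leafset()
    n = len(labels)
    if n < 2:
        raise ValidationError("centroid edge needs a tree with at least 2 leaves")
    root = t.node_for_taxon(min(labels))
    below, parent, order = leafsets_below(t, root)

    best = None
    best_key = None
    for u in order:
        if parent[u] is None:
            continue
        side = below[u]
        imbalance = abs(n - 2 * len(side))
        smaller = side if len(side) * 2 <= n else labels - side
        key = (imbalance, min(smaller), len(smaller))
        if best_key is None or key < best_key or (
            key == best_key and tuple(sorted(smaller)) < best[1]
        ):
            best = ((u, parent[u]), tuple(sorted(smaller)))
            best_key = key
    return best[0]


def centroid_decomposition(t: Tree, B: int) -> Decomposition:
    """Recursively cut at centroid edges until every part has <= B leaves.

    A tree with at most ``B`` leaves yields a single subset; ``B = 1``
    bottoms out at singletons.  Subsets are returned sorted by their
    smallest taxon.
    """
    if B < 1:
        raise ValidationError(f"subset size bound must be >= 1, got {B}")
    subsets: list[frozenset[str]] = []
    stack = [t.copy()]
    while stack:
        part = stack.pop()
        if len(part.leafset()) <= B:
            subsets.append(part.leafset())
            continue
        edge = centroid_edge(part)
        left, right = split_on_edge(part, edge)
        stack.append(left)
        stack.append(right)
    subsets.sort(key=min)
    return Decomposition(subsets=subsets, max_size=B)
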