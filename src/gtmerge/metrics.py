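"""Bipartition distances between trees on a shared leafset.

Two asymmetric counts underpin everything here.  The false-negative
(FN) distance of tree ``a`` to tree ``b`` counts the nontrivial
bipartitions of ``b`` missing from ``a``; it is the criterion the
merge algorithm optimizes, chosen over the symmetric Robinson-Foulds
(RF) distance because inputs may be non-binary (a polytomy loses
bipartitions without asserting wrong ones).  RF is the symmetric
difference, and the conventional normalization divides RF by
``2N - 6``, the largest value attainable by two binary trees on ``N``
leaves.
"""

from __future__ import annotations

from .errors import ValidationError
from .trees import Tree, bipartitions


def _check_leafsets(a: Tree, b: Tree) -> None:
    la, lb = a.leafset(), b.leafset()
    if la != lb:
        raise ValidationError(
            "trees are on different leafsets "
            f"(only in first: {sorted(la - lb)[:5]!r}, "
            f"only in second: {sorted(lb - la)[:5]!r})"
        )


def fn_distance(a: Tree, b: Tree) -> int:
    """Number of nontrivial bipartitions of ``b`` absent from ``a``.

    Asymmetric: ``fn_distance(a, b) == 0`` iff every bipartition of
    ``b`` appears in ``a``.
    """
    _check_leafsets(a, b)
    return len(bipartitions(b) - bipartitions(a))


def rf_distance(a: Tree, b: Tree) -> int:
    """Robinson-Foulds distance: ``|C(a) symmetric-difference C(b)|``."""
    _check_leafsets(a, b)
    return len(bipartitions(a) ^ bipartitions(b))


def normalized_rf_error(estimated: Tree, true_tree: Tree) -> float:
    """RF distance divided by ``2N - 6``.

    0 means a perfect topological match; 1 means two binary trees with
    no nontrivial bipartition in common.  Requires ``N >= 4`` (smaller
    trees have no nontrivial bipartitions to compare).
    """
    _check_leafsets(estimated, true_tree)
    n = len(true_tree.leafset())
    if n < 4:
        raise ValidationError(f"normalized RF needs at least 4 leaves, got {n}")
    return rf_distance(estimated, true_tree) / (2 * n - 6)
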