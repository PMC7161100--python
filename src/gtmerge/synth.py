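"""Seeded synthetic fixtures: random trees, perturbed guides, full instances.

The generator emulates the input shape of a divide-and-conquer species
tree pipeline: a true binary tree on ``n`` taxa, constraint trees
obtained as its induced subtrees under a centroid decomposition (so
they are correct by construction), and a guide tree whose topological
error is controlled by a number of random nearest-neighbour
interchange (NNI) moves away from the truth.  NNI is used because its
effect on the Robinson-Foulds distance is bounded (at most 2 per
move), giving a clean error dial; it does not emulate the correlated,
branch-length-dependent errors of real estimated trees.
"""

from __future__ import annotations

import random
from typing import NamedTuple, Sequence

from .decompose import Decomposition, centroid_decomposition
from .errors import ValidationError
from .trees import Tree, restrict


def random_binary_tree(taxa: Sequence[str], seed: int) -> Tree:
    """Uniformly random unrooted binary topology on the given taxa.

    Built by sequential random leaf attachment: starting from the
    unique 3-leaf tree, each further leaf subdivides an edge chosen
    uniformly at random, which yields the uniform distribution over
    unrooted binary topologies.  Deterministic per seed.
    """
    taxa = list(taxa)
    if len(set(taxa)) != len(taxa):
        raise ValidationError("taxon labels must be unique")
    if not taxa:
        raise ValidationError("need at least one taxon")
    rng = random.Random(seed)
    t = Tree()
    if len(taxa) == 1:
        t.new_node(taxa[0])
        return t
    a = t.new_node(taxa[0])
    b = t.new_node(taxa[1])
    if len(taxa) == 2:
        t.add_edge(a, b)
        return t
    center = t.new_node()
    c = t.new_node(taxa[2])
    t.add_edge(center, a)
    t.add_edge(center, b)
    t.add_edge(center, c)
    edges = [(center, a), (center, b), (center, c)]
    for name in taxa[3:]:
        i = rng.randrange(len(edges))
        u, v = edges[i]
        w = t.new_node()
        leaf = t.new_node(name)
        t.remove_edge(u, v)
        t.add_edge(u, w)
        t.add_edge(w, v)
        t.add_edge(w, leaf)
        edges[i] = (u, w)
        edges.append((w, v))
        edges.append((w, leaf))
    return t


def perturb_nni(t: Tree, moves: int, seed: int) -> Tree:
    """Apply random NNI moves to a binary tree.

    Each move picks a random internal edge and swaps one subtree from
    each end across it, changing exactly one bipartition; hence
    ``rf_distance(t, result) <= 2 * moves``.  ``moves = 0`` returns an
    identical copy.
    """
    if moves < 0:
        raise ValidationError("number of NNI moves must be >= 0")
    for u in t.nodes:
        if not t.is_leaf(u) and t.degree(u) != 3:
            raise ValidationError("NNI perturbation requires a binary tree")
    r = t.copy()
    rng = random.Random(seed)
    for _ in range(moves):
        internal = r.internal_edges()
        if not internal:
            break
        u, v = internal[rng.randrange(len(internal))]
        side_u = [w for w in r.neighbors(u) if w != v]
        side_v = [w for w in r.neighbors(v) if w != u]
        x = side_u[rng.randrange(2)]
        y = side_v[rng.randrange(2)]
        lx = r.edge_length(u, x)
        ly = r.edge_length(v, y)
        r.remove_edge(u, x)
        r.remove_edge(v, y)
        r.add_edge(u, y, ly)
        r.add_edge(v, x, lx)
    return r


class Instance(NamedTuple):
    """A complete synthetic merge problem."""

    true_tree: Tree
    guide: Tree
    constraints: list[Tree]
    decomposition: Decomposition


def default_taxa(n: int) -> list[str]:
    """Zero-padded taxon names whose lexicographic order is numeric."""
    width = len(str(n))
    return [f"t{i:0{width}d}" for i in range(1, n + 1)]


def make_instance(n: int, B: int, guide_error_moves: int, seed: int) -> Instance:
    """Generate a pipeline-shaped merge instance.

    The true tree is a random binary tree on ``n`` taxa; constraints
    are its induced subtrees under a centroid decomposition with bound
    ``B``; the guide is the true tree perturbed by
    ``guide_error_moves`` NNI moves.  With zero moves the guide is the
    truth and the merge must reproduce it exactly.
    """
    if n < 4:
        raise ValidationError(f"instance needs n >= 4 taxa, got {n}")
    if not 1 <= B <= n:
        raise ValidationError(f"subset bound must satisfy 1 <= B <= n, got {B}")
    rng = random.Random(seed)
    tree_seed = rng.randrange(2**31)
    nni_seed = rng.randrange(2**31)
    true_tree = random_binary_tree(default_taxa(n), tree_seed)
    decomposition = centroid_decomposition(true_tree, B)
    constraints = [restrict(true_tree, s) for s in decomposition.subsets]
    guide = perturb_nni(true_tree, guide_error_moves, nni_seed)
    return Instance(true_tree, guide, constraints, decomposition)
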