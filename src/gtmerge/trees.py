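"""Unrooted leaf-labelled phylogenetic trees and edge surgery.

The :class:`Tree` here is the one tree object used throughout the
package: it represents guide trees, constraint trees, and merged
supertrees alike.  Trees are unrooted and possibly multifurcating;
every topological operation ignores branch lengths, which are carried
through I/O as inert annotations.  Degree-2 nodes are never allowed to
persist: they are suppressed on construction and after every surgery,
so that the edge set of a tree corresponds one-to-one with its
bipartitions.

Newick reading is delegated to dendropy; writing is done here so that
output is deterministic (children ordered by their smallest descendant
taxon), which makes merge results byte-reproducible.
"""

from __future__ import annotations

import io
import re
from typing import Iterable, Iterator, Optional, Union

import dendropy

from .errors import NewickError, ValidationError

Edge = tuple[int, int]
#: An attachment site: either an edge (node-id pair) or a bare node id,
#: the latter used for single-node components that have no edges.
EdgeOrVertex = Union[Edge, int]


class Bipartition:
    """An orientation-free split ``A|B`` of a reference leafset.

    Deleting any edge of a tree partitions the leaf labels into two
    blocks; this class is the canonical, hashable form of that split.
    Equality is orientation-free (``A|B == B|A``) and two bipartitions
    over different reference leafsets never compare equal, because the
    reference leafset is exactly ``side_a | side_b``.

    Canonicalization: ``side_a`` is the block containing the
    lexicographically smallest taxon of the reference leafset.
    """

    __slots__ = ("side_a", "side_b", "_hash")

    def __init__(self, side_a: Iterable[str], side_b: Iterable[str]):
        a = frozenset(side_a)
        b = frozenset(side_b)
        if a & b:
            raise ValidationError(
                f"bipartition sides overlap: {sorted(a & b)!r}"
            )
        if not (a or b):
            raise ValidationError("bipartition over an empty leafset")
        if not a or (b and min(b) < min(a)):
            a, b = b, a
        self.side_a = a
        self.side_b = b
        self._hash = hash((a, b))

    @property
    def leafset(self) -> frozenset[str]:
        """The reference leafset, ``side_a | side_b``."""
        return self.side_a | self.side_b

    def is_trivial(self) -> bool:
        """True iff one side has at most one taxon.

        Trivial splits are induced by pendant edges (or by restriction
        to a small taxon subset); they are present in every tree on the
        same leafset and therefore never contribute to bipartition
        distances.
        """
        return min(len(self.side_a), len(self.side_b)) <= 1

    def restrict(self, taxa: Iterable[str]) -> "Bipartition":
        """The induced split on a taxon subset (``pi`` restricted to ``taxa``)."""
        taxa = frozenset(taxa)
        if not taxa <= self.leafset:
            raise ValidationError("restriction taxa not a subset of the leafset")
        return Bipartition(self.side_a & taxa, self.side_b & taxa)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Bipartition):
            return NotImplemented
        return self.side_a == other.side_a and self.side_b == other.side_b

    def __hash__(self) -> int:
        return self._hash

    def __repr__(self) -> str:
        fmt = lambda s: ",".join(sorted(s))
        return f"Bipartition({fmt(self.side_a)} | {fmt(self.side_b)})"


class Tree:
    """Unrooted, leaf-labelled, possibly multifurcating tree.

    Nodes are opaque integer ids; adjacency maps each node to its
    neighbours with an optional branch length per edge.  Invariants
    maintained by every public operation:

    * connected and acyclic;
    * every leaf (labelled node) has degree 1, except in the
      single-node tree;
    * no unlabelled node of degree < 3.
    """

    __slots__ = ("_adj", "leaf_label", "internal_label", "_label2node", "_next_id")

    def __init__(self):
        self._adj: dict[int, dict[int, Optional[float]]] = {}
        self.leaf_label: dict[int, str] = {}
        self.internal_label: dict[int, str] = {}
        self._label2node: dict[str, int] = {}
        self._next_id = 0

    # -- construction ---------------------------------------------------

    def new_node(self, label: Optional[str] = None) -> int:
        nid = self._next_id
        self._next_id += 1
        self._adj[nid] = {}
        if label is not None:
            if label in self._label2node:
                raise ValidationError(f"duplicate leaf label {label!r}")
            self.leaf_label[nid] = label
            self._label2node[label] = nid
        return nid

    def add_edge(self, u: int, v: int, length: Optional[float] = None) -> None:
        if u == v:
            raise ValidationError("self-loop edge")
        if u not in self._adj or v not in self._adj:
            raise ValidationError("edge endpoint is not a node of this tree")
        if v in self._adj[u]:
            raise ValidationError("parallel edge")
        self._adj[u][v] = length
        self._adj[v][u] = length

    def remove_edge(self, u: int, v: int) -> None:
        try:
            del self._adj[u][v]
            del self._adj[v][u]
        except KeyError:
            raise ValidationError(f"({u}, {v}) is not an edge") from None

    def remove_node(self, u: int) -> None:
        for w in list(self._adj[u]):
            del self._adj[w][u]
        del self._adj[u]
        if u in self.leaf_label:
            del self._label2node[self.leaf_label.pop(u)]
        self.internal_label.pop(u, None)

    # -- queries --------------------------------------------------------

    @property
    def nodes(self) -> Iterator[int]:
        return iter(self._adj)

    @property
    def n_nodes(self) -> int:
        return len(self._adj)

    def neighbors(self, u: int) -> list[int]:
        return list(self._adj[u])

    def degree(self, u: int) -> int:
        return len(self._adj[u])

    def has_edge(self, u: int, v: int) -> bool:
        return v in self._adj.get(u, ())

    def edge_length(self, u: int, v: int) -> Optional[float]:
        if not self.has_edge(u, v):
            raise ValidationError(f"({u}, {v}) is not an edge")
        return self._adj[u][v]

    def edges(self) -> list[Edge]:
        return [(u, v) for u in self._adj for v in self._adj[u] if u < v]

    def internal_edges(self) -> list[Edge]:
        """Edges with no leaf endpoint; exactly these induce nontrivial splits."""
        return [
            (u, v)
            for (u, v) in self.edges()
            if u not in self.leaf_label and v not in self.leaf_label
        ]

    def is_leaf(self, u: int) -> bool:
        return u in self.leaf_label

    def leaves(self) -> list[int]:
        return list(self.leaf_label)

    def leafset(self) -> frozenset[str]:
        return frozenset(self._label2node)

    def node_for_taxon(self, name: str) -> int:
        try:
            return self._label2node[name]
        except KeyError:
            raise ValidationError(f"taxon {name!r} not in tree") from None

    # -- copying & invariants -------------------------------------------

    def copy(self) -> "Tree":
        t = Tree()
        t._adj = {u: dict(nbrs) for u, nbrs in self._adj.items()}
        t.leaf_label = dict(self.leaf_label)
        t.internal_label = dict(self.internal_label)
        t._label2node = dict(self._label2node)
        t._next_id = self._next_id
        return t

    def suppress_node(self, v: int) -> None:
        """Splice out an unlabelled degree-2 node, concatenating lengths."""
        if v in self.leaf_label or self.degree(v) != 2:
            raise ValidationError("can only suppress an unlabelled degree-2 node")
        (a, la), (b, lb) = self._adj[v].items()
        self.remove_node(v)
        if la is None and lb is None:
            length = None
        else:
            length = (la or 0.0) + (lb or 0.0)
        self.add_edge(a, b, length)

    def _suppress_all_degree2(self) -> None:
        for v in [v for v in self._adj if v not in self.leaf_label]:
            if len(self._adj[v]) == 2:
                self.suppress_node(v)

    def check_valid(self) -> None:
        """Raise :class:`ValidationError` if any structural invariant fails."""
        if self.n_nodes == 0:
            raise ValidationError("empty tree")
        n_edges = sum(len(a) for a in self._adj.values()) // 2
        if n_edges != self.n_nodes - 1:
            raise ValidationError("edge count inconsistent with a tree")
        start = next(iter(self._adj))
        seen = {start}
        stack = [start]
        while stack:
            u = stack.pop()
            for w in self._adj[u]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        if len(seen) != self.n_nodes:
            raise ValidationError("tree is not connected")
        for u in self._adj:
            d = len(self._adj[u])
            if u in self.leaf_label:
                if d > 1 or (d == 0 and self.n_nodes > 1):
                    raise ValidationError(f"leaf node {u} has degree {d}")
            else:
                if d < 3:
                    raise ValidationError(
                        f"unlabelled internal node {u} has degree {d}"
                    )

    def __repr__(self) -> str:
        return f"<Tree n_leaves={len(self.leaf_label)} n_nodes={self.n_nodes}>"


# -- traversal helpers ---------------------------------------------------


def _preorder(t: Tree, root: int) -> tuple[list[int], dict[int, Optional[int]]]:
    """Preorder node list and parent map for ``t`` rooted at ``root``.

    ``reversed(order)`` visits children before parents (a postorder).
    """
    parent: dict[int, Optional[int]] = {root: None}
    order = []
    stack = [root]
    while stack:
        u = stack.pop()
        order.append(u)
        for w in t._adj[u]:
            if w not in parent:
                parent[w] = u
                stack.append(w)
    return order, parent


def leafsets_below(t: Tree, root: int) -> tuple[dict[int, frozenset[str]], dict[int, Optional[int]], list[int]]:
    """Per-node descendant leaf-label sets for ``t`` rooted at ``root``.

    For every node ``u != root``, ``below[u]`` is the leafset on the
    far side of the edge ``(u, parent[u])`` as seen from the root.
    """
    order, parent = _preorder(t, root)
    below: dict[int, frozenset[str]] = {}
    for u in reversed(order):
        if t.is_leaf(u):
            s = frozenset((t.leaf_label[u],))
        else:
            s = frozenset()
        for w in t._adj[u]:
            if w != parent[u]:
                s |= below[w]
        below[u] = s
    return below, parent, order


# -- newick I/O ----------------------------------------------------------


def parse_newick(text: str) -> Tree:
    """Parse one newick string into an unrooted :class:`Tree`.

    Rooted newick (the common on-disk form) is accepted; a degree-2
    root is suppressed so that the result is genuinely unrooted.
    Branch lengths and internal labels are retained as inert
    annotations.
    """
    text = text.strip()
    if not text:
        raise NewickError("empty newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickError(f"newick parse failed: {exc}") from exc

    t = Tree()
    node_id: dict = {}
    for nd in dtree.preorder_node_iter():
        if nd.is_leaf():
            if nd.taxon is None or not nd.taxon.label:
                raise NewickError("leaf without a label")
            nid = t.new_node(nd.taxon.label)
        else:
            nid = t.new_node()
            if nd.label:
                t.internal_label[nid] = nd.label
        node_id[nd] = nid
        if nd.parent_node is not None:
            t.add_edge(node_id[nd.parent_node], nid, nd.edge.length)
    # redundant nesting like "((a,b));" leaves unlabelled dangling nodes
    dangling = [u for u in t._adj if not t.is_leaf(u) and t.degree(u) <= 1]
    while dangling:
        u = dangling.pop()
        nbrs = t.neighbors(u)
        t.remove_node(u)
        for w in nbrs:
            if not t.is_leaf(w) and t.degree(w) <= 1:
                dangling.append(w)
    t._suppress_all_degree2()
    t.check_valid()
    return t


def parse_newick_file(path) -> list[Tree]:
    """Read one or more newick trees (one per line / per ``;``) from a file."""
    with io.open(path, "r", encoding="utf-8") as fh:
        content = fh.read()
    trees = []
    for chunk in content.split(";"):
        if chunk.strip():
            trees.append(parse_newick(chunk + ";"))
    if not trees:
        raise NewickError(f"no trees found in {path}")
    return trees


_SAFE_LABEL = re.compile(r"[^()\[\]{}/\\,;:=*'\"`+<> \t\n]+")


def _escape_label(label: str) -> str:
    if _SAFE_LABEL.fullmatch(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_newick(t: Tree) -> str:
    """Serialize to newick with a deterministic layout.

    The tree is written from the internal node adjacent to the
    lexicographically smallest taxon, with sibling subtrees ordered by
    their smallest descendant taxon, so identical trees always produce
    identical text.
    """
    t.check_valid()
    labels = sorted(t._label2node)
    if not labels:
        raise ValidationError("cannot write a tree with no leaves")
    if len(labels) == 1:
        return _escape_label(labels[0]) + ";"
    first = t.node_for_taxon(labels[0])
    if len(labels) == 2:
        length = t.edge_length(first, t.node_for_taxon(labels[1]))
        suffix = "" if length is None else f":{length:g}"
        return (
            f"({_escape_label(labels[0])},"
            f"{_escape_label(labels[1])}{suffix});"
        )

    center = t.neighbors(first)[0]
    order, parent = _preorder(t, center)
    # bottom-up: newick fragment and smallest descendant taxon per node
    frag: dict[int, str] = {}
    mintax: dict[int, str] = {}
    for u in reversed(order):
        length = None if parent[u] is None else t.edge_length(u, parent[u])
        suffix = "" if length is None else f":{length:g}"
        if t.is_leaf(u):
            mintax[u] = t.leaf_label[u]
            frag[u] = _escape_label(t.leaf_label[u]) + suffix
        else:
            kids = sorted(
                (w for w in t._adj[u] if w != parent[u]),
                key=lambda w: mintax[w],
            )
            mintax[u] = min(mintax[w] for w in kids)
            inner = ",".join(frag[w] for w in kids)
            lab = _escape_label(t.internal_label[u]) if u in t.internal_label else ""
            frag[u] = f"({inner}){lab}{suffix}"
    return frag[center] + ";"


# -- topological operations ----------------------------------------------


def bipartitions(t: Tree, include_trivial: bool = False) -> set[Bipartition]:
    """The bipartition set C(t): one split per edge.

    By default only nontrivial splits are returned; a binary tree on
    ``n`` leaves then yields exactly ``n - 3`` of them.
    """
    labels = t.leafset()
    if len(labels) < 2:
        return set()
    root = t.node_for_taxon(min(labels))
    below, parent, order = leafsets_below(t, root)
    out: set[Bipartition] = set()
    for u in order:
        if parent[u] is None:
            continue
        bp = Bipartition(below[u], labels - below[u])
        if include_trivial or not bp.is_trivial():
            out.add(bp)
    return out


def restrict(t: Tree, taxa: Iterable[str]) -> Tree:
    """Homeomorphic subtree induced by ``taxa`` (degree-2 nodes suppressed).

    Every nontrivial bipartition of the result is the restriction of
    some bipartition of ``t`` to ``taxa``.
    """
    taxa = frozenset(taxa)
    if not taxa:
        raise ValidationError("cannot restrict to an empty taxon set")
    missing = taxa - t.leafset()
    if missing:
        raise ValidationError(f"taxa not in tree: {sorted(missing)!r}")
    r = t.copy()
    doomed = [u for u, lab in r.leaf_label.items() if lab not in taxa]
    while doomed:
        u = doomed.pop()
        nbrs = r.neighbors(u)
        r.remove_node(u)
        for w in nbrs:
            if not r.is_leaf(w) and r.degree(w) <= 1:
                doomed.append(w)
    r._suppress_all_degree2()
    # a surviving unlabelled degree-0 node cannot occur: taxa is nonempty
    r.check_valid()
    return r


def collapse_edges(t: Tree, edges: Iterable[Edge]) -> Tree:
    """Contract the given internal edges, removing their bipartitions.

    The leafset is unchanged; contracting edges around a node creates a
    polytomy.  Pendant edges cannot be collapsed (that would orphan a
    leaf).
    """
    r = t.copy()
    merged: dict[int, int] = {}

    def find(u: int) -> int:
        while u in merged:
            u = merged[u]
        return u

    for (u, v) in edges:
        if not t.has_edge(u, v):
            raise ValidationError(f"({u}, {v}) is not an edge of the tree")
        if t.is_leaf(u) or t.is_leaf(v):
            raise ValidationError("cannot collapse a pendant edge")
        fu, fv = find(u), find(v)
        if fu == fv:
            continue
        # merge fv into fu
        for w, length in list(r._adj[fv].items()):
            r.remove_edge(fv, w)
            if w != fu:
                r.add_edge(fu, w, length)
        r.remove_node(fv)
        merged[fv] = fu
    r.check_valid()
    return r


def _resolve_site(out: Tree, t: Tree, site: EdgeOrVertex, idmap: dict[int, int]) -> int:
    """Return the node of ``out`` at which to attach: a subdivision point
    of an edge site, or the mapped node of a vertex site."""
    if isinstance(site, tuple):
        u, v = site
        if not t.has_edge(u, v):
            raise ValidationError(f"attachment edge ({u}, {v}) not in tree")
        mu, mv = idmap[u], idmap[v]
        w = out.new_node()
        out.remove_edge(mu, mv)
        # subdivision halves deliberately carry no length
        out.add_edge(mu, w)
        out.add_edge(w, mv)
        return w
    if site not in t._adj:
        raise ValidationError(f"attachment vertex {site} not in tree")
    return idmap[site]


def subdivide_and_join(t1: Tree, e1: EdgeOrVertex, t2: Tree, e2: EdgeOrVertex) -> Tree:
    """Connect two leaf-disjoint trees by one new edge.

    Each attachment site is either an edge — subdivided to create the
    endpoint of the new edge — or a bare node (used for single-node
    components, which have no edges).  The result restricted to either
    input leafset is that input tree again, and the single new edge is
    the only edge inducing the split ``L(t1) | L(t2)``.
    """
    overlap = t1.leafset() & t2.leafset()
    if overlap:
        raise ValidationError(f"leafsets overlap: {sorted(overlap)!r}")
    out = Tree()
    map1 = {u: out.new_node(t1.leaf_label.get(u)) for u in t1._adj}
    for u, v in t1.edges():
        out.add_edge(map1[u], map1[v], t1.edge_length(u, v))
    map2 = {u: out.new_node(t2.leaf_label.get(u)) for u in t2._adj}
    for u, v in t2.edges():
        out.add_edge(map2[u], map2[v], t2.edge_length(u, v))
    for src, mp in ((t1, map1), (t2, map2)):
        for u, lab in src.internal_label.items():
            out.internal_label[mp[u]] = lab
    a = _resolve_site(out, t1, e1, map1)
    b = _resolve_site(out, t2, e2, map2)
    out.add_edge(a, b)
    out.check_valid()
    return out


def split_on_edge(t: Tree, edge: Edge) -> tuple[Tree, Tree]:
    """Delete an edge and return the two component subtrees.

    Node ids are preserved.  An endpoint left with degree 2 is
    suppressed; an endpoint that was a leaf becomes a single-node tree.
    Returned in the order (side of ``edge[0]``, side of ``edge[1]``).
    """
    u, v = edge
    if not t.has_edge(u, v):
        raise ValidationError(f"({u}, {v}) is not an edge of the tree")

    def extract(start: int, forbidden: int) -> Tree:
        part = Tree()
        part._next_id = t._next_id
        seen = {start}
        stack = [start]
        while stack:
            x = stack.pop()
            part._adj[x] = {}
            if x in t.leaf_label:
                part.leaf_label[x] = t.leaf_label[x]
                part._label2node[t.leaf_label[x]] = x
            if x in t.internal_label:
                part.internal_label[x] = t.internal_label[x]
            for w in t._adj[x]:
                if (x, w) in ((start, forbidden), (forbidden, start)):
                    continue
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        for x in part._adj:
            for w, length in t._adj[x].items():
                if w in part._adj and not ((x, w) in ((u, v), (v, u))):
                    part._adj[x][w] = length
        if not part.is_leaf(start) and part.degree(start) == 2:
            part.suppress_node(start)
        part.check_valid()
        return part

    return extract(u, v), extract(v, u)
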