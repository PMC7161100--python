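# gtmerge

Merging leaf-disjoint phylogenetic trees into a single supertree, guided
by a (possibly imperfect) tree on the full taxon set.

## The problem

Large-scale species tree estimation is often run divide-and-conquer
style: compute a fast *starting tree* on all N taxa, cut its taxon set
into disjoint subsets (each small enough for an expensive, accurate
method), re-estimate a tree on each subset, and then merge the subset
trees back into one tree on all N taxa. The merge step is the delicate
part: the subset trees are on pairwise-disjoint leaf sets, so a
*compatibility supertree* — a tree `T` with `T|L(t_i) = t_i` for every
input tree `t_i` — always exists, but almost all of them are terrible.
Auxiliary information must pick a good one.

`gtmerge` uses a **guide tree** `T*` on the full taxon set as that
auxiliary information. Writing `C(t)` for the set of nontrivial
bipartitions (splits) induced by the edges of `t`, and

```
FN(T, T*) = |C(T*) \ C(T)|
```

for the false-negative distance of `T` to `T*`, it solves

> among all compatibility supertrees of the constraint trees
> `t_1, …, t_k` **formed by adding connecting edges between them**
> (unblended mergers), return one minimizing `FN(T, T*)`

exactly, in near-quadratic time. The restriction to unblended mergers
is what makes the problem tractable — the unrestricted variant is
NP-hard — and costs little in practice, though not nothing: there are
guides none of whose splits survive any unblended merger (see the
worked example below). The algorithm (1) collapses every guide edge
whose split contradicts a constraint tree, (2) collapses every edge
spanned by two or more constraint leaf sets (a convexity violation),
and (3) recursively splits the remaining tree at bridge edges and
rejoins the constraint trees across each split, subdividing the edges
that induce the same local splits the guide had next to the cut.

The package also ships the surrounding pipeline machinery: centroid
edge decomposition (cutting a starting tree into subsets of at most
`B` taxa), RF / FN bipartition distances with the standard `2N − 6`
normalization, a seeded synthetic-instance generator, and a
brute-force oracle that enumerates *all* unblended mergers so the
optimality claim is testable.

## Worked example

The classic case where unblended merging provably cannot win. The
guide is an 8-taxon caterpillar and the two constraint trees interleave
along it:

```python
from gtmerge import parse_newick, gtm, best_unblended, write_newick

guide = parse_newick("(1,(2,(3,(4,(5,(6,(7,8)))))));")
t1    = parse_newick("(1,(5,(6,7)));")   # = guide restricted to {1,5,6,7}
t2    = parse_newick("(2,(3,(4,8)));")   # = guide restricted to {2,3,4,8}

result = gtm(guide, [t1, t2])
print(write_newick(result.supertree))    # (1,(2,(3,(4,8))),(5,(6,7)));
print(result.fn_to_guide)                # 5
print(result.collapsed_convexity_violations)  # 5
print(best_unblended([t1, t2], guide)[1])     # 5
```

The guide *is* a compatibility supertree of `{t1, t2}` — but a blended
one. Every one of its 5 internal edges is spanned by both constraint
sets, so all are collapsed, and no unblended merger can recover any of
them: the merge returns FN 5, and the brute-force scan of all 25
attachment choices confirms that 5 is optimal.

Or from the shell:

```
gtmerge merge --guide guide.nwk --report report.json c1.nwk c2.nwk
gtmerge rf --tree1 a.nwk --tree2 b.nwk --normalized
gtmerge decompose --tree start.nwk --max-size 120 --output-dir subsets/
gtmerge synth --n 64 --max-size 16 --guide-moves 10 --seed 7 --output-dir fixture/
```

Exit codes: 0 success, 2 invalid input, 3 internal invariant failure.

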