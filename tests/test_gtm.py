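"""The guide-tree merge algorithm: classification, collapse, rejoin."""

import random

import pytest

from gtmerge import (
    Bipartition,
    EdgeKind,
    InvariantError,
    ValidationError,
    bipartitions,
    classify_edge,
    collapse_phase,
    find_attachment_edge,
    fn_distance,
    gtm,
    is_compatibility_supertree,
    parse_newick,
    rejoin,
    restrict,
    rf_distance,
    validate_inputs,
    violates_constraint,
    write_newick,
)
from gtmerge.synth import make_instance
from gtmerge.trees import leafsets_below


class TestValidateInputs:
    def test_worked_example_taxon_map(self, caterpillar8, half1, half2):
        m = validate_inputs(caterpillar8, [half1, half2])
        assert {x for x, i in m.items() if i == 0} == {"1", "5", "6", "7"}
        assert {x for x, i in m.items() if i == 1} == {"2", "3", "4", "8"}

    def test_overlapping_constraints_rejected(self):
        g = parse_newick("(a,b,c);")
        with pytest.raises(ValidationError, match="'b'"):
            validate_inputs(g, [parse_newick("(a,b);"), parse_newick("(b,c);")])

    def test_incomplete_cover_rejected(self, caterpillar8, half1):
        with pytest.raises(ValidationError, match="missing"):
            validate_inputs(caterpillar8, [half1])

    def test_single_constraint_covering_everything(self, caterpillar8):
        c = parse_newick("((1,2),(3,4),((5,6),(7,8)));")
        validate_inputs(caterpillar8, [c])
        result = gtm(caterpillar8, [c])
        assert rf_distance(result.supertree, c) == 0
        assert result.fn_to_guide == fn_distance(c, caterpillar8)


class TestClassifyEdge:
    @pytest.fixture
    def small_guide(self):
        return parse_newick("(a,b,(c,(d,e)));")

    @pytest.fixture
    def small_map(self):
        return {"a": 0, "b": 0, "c": 0, "d": 1, "e": 1}

    def _edge_with_side(self, t, names):
        root = t.node_for_taxon(min(t.leafset()))
        below, parent, order = leafsets_below(t, root)
        for u in order:
            if parent[u] is None:
                continue
            if below[u] == names or t.leafset() - below[u] == names:
                return (u, parent[u])
        raise AssertionError(f"no edge with side {names}")

    def test_edge_separating_whole_sets_is_bridge(self, small_guide, small_map):
        e = self._edge_with_side(small_guide, frozenset("de"))
        assert classify_edge(small_guide, e, small_map).kind == EdgeKind.BRIDGE

    def test_pendant_edge_lies_within_its_set(self, small_guide, small_map):
        e = self._edge_with_side(small_guide, frozenset("d"))
        ec = classify_edge(small_guide, e, small_map)
        assert ec.kind == EdgeKind.WITHIN
        assert ec.constraint_index == 1

    def test_pendant_edge_of_singleton_set_is_bridge(self):
        g = parse_newick("(a,b,(c,d));")
        tmap = {"a": 0, "b": 0, "c": 0, "d": 1}
        e = self._edge_with_side(g, frozenset("d"))
        assert classify_edge(g, e, tmap).kind == EdgeKind.BRIDGE

    def test_all_caterpillar_internal_edges_violate_convexity(
        self, caterpillar8, half1, half2
    ):
        tmap = validate_inputs(caterpillar8, [half1, half2])
        for e in caterpillar8.internal_edges():
            ec = classify_edge(caterpillar8, e, tmap)
            assert ec.kind == EdgeKind.VIOLATES_CONVEXITY


class TestViolatesConstraint:
    quartet = "((a,b),(c,d));"

    def test_conflicting_restriction_violates(self):
        t = parse_newick(self.quartet)
        pi = Bipartition({"a", "c", "x"}, {"b", "d", "y"})
        assert violates_constraint(pi, t) is True

    def test_matching_restriction_does_not_violate(self):
        t = parse_newick(self.quartet)
        pi = Bipartition({"a", "b", "x"}, {"c", "d", "y"})
        assert violates_constraint(pi, t) is False

    def test_trivial_restriction_never_violates(self):
        t = parse_newick(self.quartet)
        pi = Bipartition({"a"}, {"b", "c", "d"})
        assert violates_constraint(pi, t) is False


class TestCollapsePhase:
    def test_convex_constraints_collapse_nothing(self):
        guide = parse_newick("((a,(b,c)),(d,(e,f)));")
        cons = [restrict(guide, set("abc")), restrict(guide, set("def"))]
        out = collapse_phase(guide, cons)
        assert bipartitions(out) == bipartitions(guide)

    def test_caterpillar_collapses_to_star(self, caterpillar8, half1, half2):
        out = collapse_phase(caterpillar8, [half1, half2])
        assert bipartitions(out) == set()
        assert out.leafset() == caterpillar8.leafset()

    def test_star_constraint_forces_collapse_of_resolving_edges(self):
        guide = parse_newick("(a,(b,(c,(d,(e,f)))));")
        cons = [parse_newick("(a,b,c,d);"), parse_newick("(e,f);")]
        out = collapse_phase(guide, cons)
        # ab|cdef restricts to ab|cd which the star lacks -> collapsed;
        # abc|def restricts trivially (abc|d); abcd|ef is a bridge
        assert {frozenset((b.side_a, b.side_b)) for b in bipartitions(out)} == {
            frozenset((frozenset("abc"), frozenset("def"))),
            frozenset((frozenset("abcd"), frozenset("ef"))),
        }

    def test_collapse_counts_reported_by_gtm(self, caterpillar8, half1, half2):
        result = gtm(caterpillar8, [half1, half2])
        assert result.collapsed_constraint_violations == 0
        assert result.collapsed_convexity_violations == 5


class TestRejoin:
    def test_single_constraint_returned_verbatim(self):
        c = parse_newick("((a,b),(c,d));")
        out = rejoin(c.copy(), [c])
        assert rf_distance(out, c) == 0

    def test_two_convex_halves_reproduce_the_guide(self):
        guide = parse_newick("((a,(b,c)),(d,(e,f)));")
        cons = [restrict(guide, set("abc")), restrict(guide, set("def"))]
        out = rejoin(collapse_phase(guide, cons), cons)
        assert rf_distance(out, guide) == 0

    def test_polytomy_junction_is_refined_into_a_bridge(self):
        # two constraint sets meeting at one polytomy: the rejoin must
        # manufacture a separating edge and still honour both trees
        guide = parse_newick("(a1,a2,a3,b1,b2,b3);")
        cons = [parse_newick("(a1,(a2,a3));"), parse_newick("(b1,(b2,b3));")]
        out = rejoin(guide, cons)
        assert is_compatibility_supertree(out, cons)
        cross = Bipartition({"a1", "a2", "a3"}, {"b1", "b2", "b3"})
        assert cross in bipartitions(out)


class TestGtm:
    def test_convex_decomposition_recovers_guide_exactly(self):
        inst = make_instance(40, 11, 0, seed=9)
        result = gtm(inst.guide, inst.constraints)
        assert result.fn_to_guide == 0
        assert rf_distance(result.supertree, inst.guide) == 0

    def test_worked_example_cannot_reach_fn_zero(self, caterpillar8, half1, half2):
        result = gtm(caterpillar8, [half1, half2])
        assert result.fn_to_guide == 5  # every guide split needs blending
        assert is_compatibility_supertree(result.supertree, [half1, half2])

    def test_k1_returns_the_constraint(self, caterpillar8):
        c = parse_newick("((1,2),(3,4),((5,6),(7,8)));")
        result = gtm(caterpillar8, [c])
        assert rf_distance(result.supertree, c) == 0
        assert result.fn_to_guide == fn_distance(c, caterpillar8)

    def test_attachment_log_has_one_entry_per_added_edge(self):
        inst = make_instance(30, 6, 4, seed=5)
        result = gtm(inst.guide, inst.constraints)
        assert len(result.attachment_log) == len(inst.constraints) - 1

    def test_result_is_unblended(self):
        """Each constraint set occupies a connected region: no supertree
        split has two different constraint sets on both of its sides."""
        inst = make_instance(36, 9, 12, seed=17)
        result = gtm(inst.guide, inst.constraints)
        sets = [c.leafset() for c in inst.constraints]
        for b in bipartitions(result.supertree):
            spanning = sum(
                1 for s in sets if (s & b.side_a) and (s & b.side_b)
            )
            assert spanning <= 1

    def test_determinism_byte_identical(self):
        inst = make_instance(50, 13, 10, seed=23)
        a = gtm(inst.guide, inst.constraints)
        b = gtm(inst.guide, inst.constraints)
        assert write_newick(a.supertree) == write_newick(b.supertree)

    def test_random_tie_mode_is_reproducible_and_optimal(self):
        inst = make_instance(32, 8, 6, seed=2)
        det = gtm(inst.guide, inst.constraints)
        r1 = gtm(inst.guide, inst.constraints, random_ties_seed=99)
        r2 = gtm(inst.guide, inst.constraints, random_ties_seed=99)
        assert write_newick(r1.supertree) == write_newick(r2.supertree)
        assert r1.fn_to_guide == det.fn_to_guide
        assert is_compatibility_supertree(r1.supertree, inst.constraints)

    def test_compatibility_across_many_instances(self):
        rng = random.Random(123)
        for _ in range(15):
            n = rng.randint(8, 60)
            inst = make_instance(
                n, rng.randint(2, min(16, n)),
                rng.randint(0, 20), rng.randrange(2**31),
            )
            result = gtm(inst.guide, inst.constraints)
            assert is_compatibility_supertree(result.supertree, inst.constraints)
            assert result.fn_to_guide == fn_distance(result.supertree, inst.guide)


class TestFindAttachmentEdge:
    def test_pendant_split_finds_pendant_edge(self, caterpillar8):
        target = Bipartition({"3"}, set("1245678"))
        u, v = find_attachment_edge(caterpillar8, target)
        leaf = caterpillar8.node_for_taxon("3")
        assert leaf in (u, v)

    def test_middle_edge_of_caterpillar(self, caterpillar8):
        target = Bipartition(set("1234"), set("5678"))
        u, v = find_attachment_edge(caterpillar8, target)
        below, parent, _ = leafsets_below(
            caterpillar8, caterpillar8.node_for_taxon("1")
        )
        child = u if parent.get(u) == v else v
        assert below[child] in (frozenset("1234"), frozenset("5678"))

    def test_absent_split_raises_invariant_error(self, caterpillar8):
        target = Bipartition(set("1357"), set("2468"))
        with pytest.raises(InvariantError) as exc:
            find_attachment_edge(caterpillar8, target)
        assert exc.value.bipartition == target

    def test_single_leaf_tree_returns_vertex(self):
        t = parse_newick("x;")
        assert find_attachment_edge(t, Bipartition({"x"}, set())) in t.nodes
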