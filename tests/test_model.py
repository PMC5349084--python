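"""LCT validation, implied speciation, event counting, and the
locus-map/placement equivalence."""

import random

import pytest

from dlcrecon.errors import ConstraintError, CoverageError, ValidationError
from dlcrecon.generate import random_instance
from dlcrecon.model import (
    LCT,
    DuplicationPlacement,
    LeafMap,
    ReconInstance,
    SpeciesMap,
    add_implied_speciations,
    count_duplications,
    count_losses,
    bottoms,
    is_duplication_placement,
    lca_species_map,
    locus_map_from_placement,
    loss_events,
    nodes_of,
    paralogous_leaf_pairs,
    placement_from_locus_map,
    reconciliation_cost,
    score_placement,
    tops,
    validate_lct,
)
from dlcrecon.trees import RootedBinaryTree, node, parse_newick

from conftest import implied_speciation_oracle, random_valid_species_map


def _lct_from_placement(instance, species_map, edges):
    aug, ext = add_implied_speciations(
        instance.gene_tree, instance.species_tree, species_map
    )
    locus_set, locus_map = locus_map_from_placement(
        aug, DuplicationPlacement(frozenset(edges))
    )
    return LCT(aug, ext, locus_set, locus_map)


def _random_valid_lct(rng, *, min_gene=2, max_gene=8):
    """A random instance plus a valid LCT built from a valid placement
    (one covering edge per paralogous pair) and a random species map."""
    instance = random_instance(
        rng.randint(min_gene, max_gene), rng.randint(1, 6), rng.random(), rng.randrange(2**31)
    )
    species_map = random_valid_species_map(instance, rng)
    aug, ext = add_implied_speciations(
        instance.gene_tree, instance.species_tree, species_map
    )
    edges = set()
    for pair in paralogous_leaf_pairs(instance):
        path = aug.path_edges(*pair)
        if not set(path) & edges:
            edges.add(rng.choice(path))
    # some extra random cuts to vary the locus structure
    spare = [e for e in aug.edges() if e not in edges]
    for e in rng.sample(spare, min(len(spare), rng.randint(0, 3))):
        edges.add(e)
    locus_set, locus_map = locus_map_from_placement(
        aug, DuplicationPlacement(frozenset(edges))
    )
    return instance, LCT(aug, ext, locus_set, locus_map)


class TestImpliedSpeciation:
    def test_identity_when_all_on_one_species(self):
        G = parse_newick("((a,b)u,c)r;")
        S = RootedBinaryTree(node("s"))
        inst = ReconInstance(G, S, LeafMap({l: "s" for l in "abc"}))
        aug, ext = add_implied_speciations(
            G, S, SpeciesMap({x: "s" for x in G.nodes})
        )
        assert aug == G
        assert dict(ext.mapping) == {x: "s" for x in G.nodes}

    def test_two_edge_species_path_inserts_one_node(self):
        G = parse_newick("(a,b)u;")
        S = parse_newick("((s1,s2)p,s3)q;")
        M = SpeciesMap({"a": "s1", "b": "s3", "u": "q"})
        aug, ext = add_implied_speciations(G, S, M)
        inserted = set(aug.nodes) - set(G.nodes)
        assert inserted == {"a@p"}
        assert ext["a@p"] == "p"

    def test_rejects_inconsistent_species_map(self):
        G = parse_newick("(a,b)u;")
        S = parse_newick("(s1,s2)q;")
        with pytest.raises(ConstraintError):
            add_implied_speciations(
                G, S, SpeciesMap({"a": "s1", "b": "s2", "u": "s1"})
            )

    def test_canonical_idempotent_and_order_invariant(self, rng):
        """Fixpoint equals the independent per-edge subdivision oracle, is
        idempotent, and does not depend on processing order."""
        for _ in range(60):
            instance = random_instance(
                rng.randint(2, 8), rng.randint(2, 8), rng.random(), rng.randrange(2**31)
            )
            M = random_valid_species_map(instance, rng)
            aug, ext = add_implied_speciations(
                instance.gene_tree, instance.species_tree, M
            )
            o_tree, o_map = implied_speciation_oracle(
                instance.gene_tree, instance.species_tree, M
            )
            assert aug == o_tree
            assert dict(ext.mapping) == o_map
            again = add_implied_speciations(aug, instance.species_tree, ext)
            assert again[0] == aug and dict(again[1].mapping) == dict(ext.mapping)
            shuffled = add_implied_speciations(
                instance.gene_tree, instance.species_tree, M,
                order_rng=random.Random(rng.randrange(2**31)),
            )
            assert shuffled[0] == aug

    def test_every_gene_edge_crosses_each_species_edge_once(self, rng):
        """In the augmented tree, consecutive nodes along any root-to-leaf
        gene path map to species nodes at most one species edge apart."""
        instance = random_instance(6, 6, 0.4, seed=77)
        M = random_valid_species_map(instance, rng)
        aug, ext = add_implied_speciations(
            instance.gene_tree, instance.species_tree, M
        )
        S = instance.species_tree
        for v in aug.preorder():
            if v.is_root:
                continue
            lo, hi = ext[v.id], ext[v.parent.id]
            assert lo == hi or S.parent_id(lo) == hi


class TestValidateLCT:
    def test_constant_locus_no_paralogs_is_valid(self):
        instance = random_instance(4, 6, 0.0, seed=3)
        lct = _lct_from_placement(instance, lca_species_map(instance), set())
        assert validate_lct(instance, lct) == []

    def test_constraint3_shared_locus_of_paralogs(self):
        instance = random_instance(4, 2, 1.0, seed=5)
        lct = _lct_from_placement(instance, lca_species_map(instance), set())
        violations = validate_lct(instance, lct)
        assert violations and all(v.constraint == 3 for v in violations)

    def test_constraint5_double_creation(self):
        G = parse_newick("((a,b)u,c)r;")
        S = parse_newick("((A,B)p,C)q;")
        instance = ReconInstance(G, S, LeafMap({"a": "A", "b": "B", "c": "C"}))
        aug, ext = add_implied_speciations(G, S, lca_species_map(instance))
        # locus 1 "created" at both a and b: two creation nodes
        locus_map = {x: 0 for x in aug.nodes}
        locus_map["a"] = locus_map["b"] = 1
        lct = LCT(aug, ext, frozenset({0, 1}), locus_map)
        assert any(v.constraint == 5 for v in validate_lct(instance, lct))

    def test_constraint4_unused_locus(self):
        instance = random_instance(3, 4, 0.0, seed=1)
        lct = _lct_from_placement(instance, lca_species_map(instance), set())
        bad = LCT(
            lct.gene_tree, lct.species_map,
            lct.locus_set | {"ghost"}, lct.locus_map,
        )
        assert any(v.constraint == 4 for v in validate_lct(instance, bad))

    def test_partial_map_is_coverage_error(self):
        instance = random_instance(3, 4, 0.0, seed=1)
        lct = _lct_from_placement(instance, lca_species_map(instance), set())
        partial = dict(lct.locus_map)
        missing = next(iter(partial))
        del partial[missing]
        with pytest.raises(CoverageError) as err:
            validate_lct(
                instance, LCT(lct.gene_tree, lct.species_map, lct.locus_set, partial)
            )
        assert missing in err.value.missing


class TestEventCounts:
    def test_constant_locus_map_no_duplications(self):
        t = parse_newick("((a,b)u,c)r;")
        assert count_duplications(t, {x: 0 for x in t.nodes}) == 0

    def test_every_edge_changes_locus(self):
        t = parse_newick("((a,b)u,c)r;")
        loci = {"r": 0, "u": 1, "a": 2, "b": 3, "c": 4}
        assert count_duplications(t, loci) == 4

    def test_duplications_ignore_species_map(self, rng):
        """The same locus map yields the same count under any species map."""
        instance = random_instance(5, 5, 0.0, seed=11)
        maps = [random_valid_species_map(instance, rng) for _ in range(3)]
        auged = [
            add_implied_speciations(instance.gene_tree, instance.species_tree, M)
            for M in maps
        ]
        # constant locus map on each augmentation
        counts = {
            count_duplications(aug, {x: 0 for x in aug.nodes}) for aug, _ in auged
        }
        assert counts == {0}

    def test_no_losses_single_locus_full_coverage(self):
        G = parse_newick("(a,b)u;")
        S = parse_newick("(A,B)p;")
        instance = ReconInstance(G, S, LeafMap({"a": "A", "b": "B"}))
        lct = _lct_from_placement(instance, lca_species_map(instance), set())
        assert count_losses(instance, lct) == 0

    def test_single_leaf_gene_tree_zero_events(self):
        G = RootedBinaryTree(node("g"))
        S = parse_newick("((A,B)p,C)q;")
        instance = ReconInstance(G, S, LeafMap({"g": "A"}))
        lct, events = score_placement(instance)
        assert (events.duplications, events.losses, events.cost) == (0, 0, 0)

    def test_loss_counting_against_definitional_oracle(self, rng):
        """Independent oracle: evaluate the loss rule per species edge as a
        plain set comprehension over nodes/bottoms/tops."""
        for _ in range(100):
            instance, lct = _random_valid_lct(rng)
            S = instance.species_tree
            expected = 0
            for s in S.edges():
                present = {
                    lct.locus_map[g]
                    for g in tops(lct, S, s) | nodes_of(lct, s)
                }
                surviving = {lct.locus_map[g] for g in bottoms(lct, s)}
                expected += len(present - surviving)
            assert count_losses(instance, lct) == expected

    def test_tops_equals_bottoms_of_parent(self, rng):
        instance, lct = _random_valid_lct(rng)
        S = instance.species_tree
        for s in S.edges():
            assert tops(lct, S, s) == bottoms(lct, S.parent_id(s))
        assert tops(lct, S, S.root.id) == set()

    def test_cost_linearity(self, rng):
        for _ in range(20):
            instance, lct = _random_valid_lct(rng)
            instance.cost_dup, instance.cost_loss = 2, 3
            ev = reconciliation_cost(instance, lct)
            assert ev.cost == 2 * ev.duplications + 3 * ev.losses

    def test_invalid_lct_raises_with_violations(self):
        instance = random_instance(4, 2, 1.0, seed=5)
        lct = _lct_from_placement(instance, lca_species_map(instance), set())
        with pytest.raises(ValidationError) as err:
            count_losses(instance, lct)
        assert any(v.constraint == 3 for v in err.value.violations)


class TestPlacementEquivalence:
    def test_empty_placement_single_locus(self):
        t = parse_newick("((a,b)u,c)r;")
        locus_set, locus_map = locus_map_from_placement(
            t, DuplicationPlacement(frozenset())
        )
        assert locus_set == frozenset({0})
        assert set(locus_map.values()) == {0}

    def test_k_cuts_give_k_plus_one_loci(self, rng):
        for seed in range(30):
            t = parse_newick("((a,b)u,(c,d)v)r;")
            edges = rng.sample(t.edges(), rng.randint(0, 6))
            locus_set, locus_map = locus_map_from_placement(
                t, DuplicationPlacement(frozenset(edges))
            )
            assert len(locus_set) == len(edges) + 1
            assert count_duplications(t, locus_map) == len(edges)

    def test_round_trip_locus_placement_locus(self, rng):
        """Placement equivalence both ways on random augmented instances."""
        for _ in range(50):
            instance, lct = _random_valid_lct(rng)
            placement = placement_from_locus_map(lct.gene_tree, lct.locus_map)
            assert len(placement) == count_duplications(lct.gene_tree, lct.locus_map)
            _, locus_map2 = locus_map_from_placement(lct.gene_tree, placement)
            assert placement_from_locus_map(lct.gene_tree, locus_map2) == placement

    def test_constraint3_iff_separation(self, rng):
        """locus_map_from_placement satisfies constraint 3 exactly when the
        placement separates every paralogous pair."""
        for _ in range(60):
            instance = random_instance(
                rng.randint(2, 7), rng.randint(1, 4), 0.6, rng.randrange(2**31)
            )
            aug, ext = add_implied_speciations(
                instance.gene_tree, instance.species_tree, lca_species_map(instance)
            )
            edges = frozenset(
                rng.sample(aug.edges(), rng.randint(0, min(5, len(aug.edges()))))
            )
            placement = DuplicationPlacement(edges)
            locus_set, locus_map = locus_map_from_placement(aug, placement)
            lct = LCT(aug, ext, locus_set, locus_map)
            violations = [v for v in validate_lct(instance, lct) if v.constraint == 3]
            # separation must be checked on the augmented tree, where the
            # placement edges live
            aug_instance = ReconInstance(aug, instance.species_tree, instance.leaf_map)
            assert is_duplication_placement(aug_instance, placement) == (not violations)

    def test_is_placement_matches_pairwise_separates(self, rng):
        for _ in range(40):
            instance = random_instance(
                rng.randint(2, 8), rng.randint(1, 5), 0.5, rng.randrange(2**31)
            )
            G = instance.gene_tree
            edges = frozenset(rng.sample(G.edges(), rng.randint(0, len(G.edges()))))
            placement = DuplicationPlacement(edges)
            expected = all(
                any(G.separates(e, g, g2) for e in edges)
                for g, g2 in paralogous_leaf_pairs(instance)
            )
            assert is_duplication_placement(instance, placement) == expected

    def test_vacuous_without_paralogs(self):
        instance = random_instance(4, 6, 0.0, seed=2)
        assert is_duplication_placement(instance, DuplicationPlacement(frozenset()))


class TestScorePlacement:
    def test_validates_by_default(self):
        instance = random_instance(4, 2, 1.0, seed=5)
        with pytest.raises(ValidationError):
            score_placement(instance)

    def test_produced_lct_is_valid(self, rng):
        """Scoring a valid placement under a valid species map always yields
        a constraint-clean LCT."""
        for _ in range(30):
            instance = random_instance(
                rng.randint(2, 7), rng.randint(1, 5), 0.5, rng.randrange(2**31)
            )
            M = random_valid_species_map(instance, rng)
            edges = set()
            for pair in paralogous_leaf_pairs(instance):
                path = instance.gene_tree.path_edges(*pair)
                if not set(path) & edges:
                    edges.add(rng.choice(path))
            lct, events = score_placement(
                instance, M, DuplicationPlacement(frozenset(edges))
            )
            assert validate_lct(instance, lct) == []
            assert events.duplications == len(edges)
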