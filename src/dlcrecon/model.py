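"""The DLC reconciliation model.

A reconciliation between a gene tree G and a species tree S (with a leaf map
``Le: L(G) -> L(S)``) is formalized as a *labeled coalescent tree* (LCT): a
species map M assigning every gene node a species node, a finite locus set,
and a locus map assigning every gene node a locus, subject to five
constraints:

1. M extends the leaf map: ``M(g) = Le(g)`` for gene leaves g.
2. Ancestor consistency: ``M(g) <=_S M(g')`` for every child g' of g.
3. Paralogous leaves (equal leaf-map image) carry distinct loci.
4. Every locus in the locus set is used by at least one gene node.
5. Every locus is created exactly once: each locus has exactly one node
   whose parent carries a different locus, except the root's locus, which
   has none.

Events are priced per Definition-style rules: a *duplication* on edge e(g)
whenever the locus changes across it, and a *loss* on a species edge e(s)
for every locus present at the top of the branch (or arising within it) but
absent at its bottom.  Duplications depend only on the locus map; losses
depend on both maps.

The species map is fixed first, *implied speciation* nodes are then inserted
so that every gene edge crosses each species branch through an explicit
(possibly unary) gene node, and the locus map is defined on the augmented
tree.  :func:`score_placement` is the public scoring entry point and
enforces this ordering.

Placement equivalence: locus maps correspond to *duplication placements* --
edge sets separating every paralogous leaf pair -- with the duplication
count equal to the placement size.  Both directions are implemented
(:func:`placement_from_locus_map`, :func:`locus_map_from_placement`).

Coalescence events carry cost 0 throughout and are not counted.
"""

from __future__ import annotations

import random
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

from .errors import (
    ConstraintError,
    CoverageError,
    UnknownNodeError,
    ValidationError,
)
from .trees import RootedBinaryTree

# -- domain types --------------------------------------------------------


@dataclass(frozen=True)
class LeafMap:
    """Total function from gene leaves to species leaves (need not be
    one-to-one nor onto)."""

    mapping: Mapping[str, str]

    def __getitem__(self, gene_leaf: str) -> str:
        return self.mapping[gene_leaf]

    def image(self) -> Set[str]:
        return set(self.mapping.values())


@dataclass
class ReconInstance:
    """A reconciliation problem input: trees, leaf map, and event costs.

    The coalescence cost is implicitly 0.
    """

    gene_tree: RootedBinaryTree
    species_tree: RootedBinaryTree
    leaf_map: LeafMap
    cost_dup: float = 1
    cost_loss: float = 0

    def __post_init__(self) -> None:
        gene_leaves = set(self.gene_tree.leaves())
        dom = set(self.leaf_map.mapping)
        if dom != gene_leaves:
            missing = sorted(gene_leaves - dom) + sorted(dom - gene_leaves)
            raise CoverageError(
                "leaf map domain must equal the gene-tree leaf set", missing
            )
        species_leaves = set(self.species_tree.leaves())
        bad = sorted(set(self.leaf_map.mapping.values()) - species_leaves)
        if bad:
            raise CoverageError(
                f"leaf map images {bad} are not species-tree leaves", bad
            )
        if self.cost_dup < 0 or self.cost_loss < 0:
            raise ConstraintError("event costs must be non-negative")


@dataclass(frozen=True)
class SpeciesMap:
    """Total map from gene-tree nodes to species-tree nodes."""

    mapping: Mapping[str, str]

    def __getitem__(self, gene_node: str) -> str:
        return self.mapping[gene_node]


@dataclass
class LCT:
    """A labeled coalescent tree.

    ``gene_tree`` is the (implied-speciation-augmented) gene tree the maps
    are total on; carrying it makes the LCT self-contained.
    """

    gene_tree: RootedBinaryTree
    species_map: SpeciesMap
    locus_set: FrozenSet
    locus_map: Mapping[str, object]


@dataclass(frozen=True)
class DuplicationPlacement:
    """A set of non-root gene-tree edges (named by child node) separating
    every paralogous leaf pair."""

    edges: FrozenSet[str]

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(sorted(self.edges))


EMPTY_PLACEMENT = DuplicationPlacement(frozenset())


@dataclass(frozen=True)
class EventCount:
    duplications: int
    losses: int
    cost: float


@dataclass(frozen=True)
class Violation:
    """A failed LCT constraint, carrying the constraint number (1-5) and the
    witnessing node/locus ids."""

    constraint: int
    witnesses: Tuple
    message: str

    def __str__(self) -> str:
        return f"constraint {self.constraint}: {self.message}"


# -- species maps --------------------------------------------------------


def lca_species_map(instance: ReconInstance) -> SpeciesMap:
    """The most-recent (deepest) species map: every internal gene node maps
    to the lca of its descendant leaves' images.  Always satisfies
    constraints 1-2."""
    G, S = instance.gene_tree, instance.species_tree
    mapping: Dict[str, str] = {}
    for v in G.postorder():
        if v.is_leaf:
            mapping[v.id] = instance.leaf_map[v.id]
        else:
            img = mapping[v.children[0].id]
            for c in v.children[1:]:
                img = S.lca(img, mapping[c.id])
            mapping[v.id] = img
    return SpeciesMap(mapping)


def validate_species_map(
    gene_tree: RootedBinaryTree,
    species_tree: RootedBinaryTree,
    leaf_map: LeafMap,
    species_map: SpeciesMap,
) -> List[Violation]:
    """Check constraints 1-2 of the LCT definition on ``gene_tree``."""
    missing = [v.id for v in gene_tree.preorder() if v.id not in species_map.mapping]
    if missing:
        raise CoverageError("species map is not total on the gene tree", missing)
    out: List[Violation] = []
    for v in gene_tree.preorder():
        if v.is_leaf:
            if species_map[v.id] != leaf_map[v.id]:
                out.append(
                    Violation(
                        1,
                        (v.id,),
                        f"M({v.id})={species_map[v.id]} != Le({v.id})={leaf_map[v.id]}",
                    )
                )
        else:
            for c in v.children:
                if not species_tree.is_ancestor(species_map[v.id], species_map[c.id]):
                    out.append(
                        Violation(
                            2,
                            (v.id, c.id),
                            f"M({v.id})={species_map[v.id]} is not an ancestor "
                            f"of M({c.id})={species_map[c.id]}",
                        )
                    )
    return out


# -- implied speciation --------------------------------------------------


def add_implied_speciations(
    gene_tree: RootedBinaryTree,
    species_tree: RootedBinaryTree,
    species_map: SpeciesMap,
    *,
    order_rng: Optional[random.Random] = None,
) -> Tuple[RootedBinaryTree, SpeciesMap]:
    """Insert implied speciation nodes and return (augmented tree, extended map).

    A node g (with parent p) triggers an insertion when the edge descends in
    the species tree (``M(g) != M(p)``) and either (1) the species parent of
    M(g) is not M(p) -- the edge skips a species branch -- or (2) p is not a
    speciation node, i.e. p keeps some child in its own species.  The new
    node h subdivides e(g) and maps to the species parent of M(g).  The
    procedure iterates to a fixpoint; the result is order-invariant (the
    optional ``order_rng`` randomizes processing order and exists so tests
    can assert exactly that).  Inserted ids are ``<original child>@<species>``.

    The input tree is not modified.
    """
    violations = validate_species_map(
        gene_tree, species_tree, instance_leaf_map_from(gene_tree, species_map), species_map
    )
    # leaves are compared against themselves above, so only constraint 2 matters here
    violations = [v for v in violations if v.constraint == 2]
    if violations:
        raise ConstraintError(
            "species map violates ancestor consistency: "
            + "; ".join(str(v) for v in violations)
        )

    T = gene_tree.copy()
    S = species_tree
    M: Dict[str, str] = dict(species_map.mapping)

    worklist = [v.id for v in T.preorder() if not v.is_root]
    if order_rng is not None:
        order_rng.shuffle(worklist)
    while worklist:
        gid = worklist.pop()
        v = T.nodes.get(gid)
        if v is None or v.parent is None:
            continue
        mg, mp = M[v.id], M[v.parent.id]
        if mg == mp:
            continue
        sp_parent = S.parent_id(mg)
        if sp_parent != mp:
            new_species = sp_parent  # condition (1): edge skips a species branch
        else:
            parent_not_speciation = any(M[c.id] == mp for c in v.parent.children)
            if not parent_not_speciation:
                continue
            new_species = sp_parent  # condition (2): == mp here
        base = gid.split("@", 1)[0]
        hid = f"{base}@{new_species}"
        siblings = [c.id for c in v.parent.children if c is not v]
        h = T.subdivide_edge(gid, hid)
        M[hid] = new_species
        worklist.extend(siblings)
        worklist.append(hid)
        worklist.append(gid)
    return T, SpeciesMap(M)


def instance_leaf_map_from(
    gene_tree: RootedBinaryTree, species_map: SpeciesMap
) -> LeafMap:
    """The leaf map induced by restricting a species map to the leaves."""
    return LeafMap({l: species_map[l] for l in gene_tree.leaves()})


# -- node partitions per species branch ----------------------------------


def nodes_of(lct: LCT, s: str) -> Set[str]:
    """Gene nodes mapped to species node ``s``."""
    return {v.id for v in lct.gene_tree.preorder() if lct.species_map[v.id] == s}


def bottoms(lct: LCT, s: str) -> Set[str]:
    """Members of ``nodes_of(s)`` that are leaves or whose children all map
    to proper descendants of ``s``."""
    out = set()
    for v in lct.gene_tree.preorder():
        if lct.species_map[v.id] != s:
            continue
        if v.is_leaf or all(lct.species_map[c.id] != s for c in v.children):
            out.add(v.id)
    return out


def tops(lct: LCT, species_tree: RootedBinaryTree, s: str) -> Set[str]:
    """``tops(s) = bottoms(p(s))``; empty for the species root."""
    p = species_tree.parent_id(s)
    if p is None:
        return set()
    return bottoms(lct, p)


# -- event counting ------------------------------------------------------


def count_duplications(gene_tree: RootedBinaryTree, locus_map: Mapping) -> int:
    """Number of non-root nodes whose locus differs from their parent's.
    Depends only on the locus map, never on the species map."""
    missing = [v.id for v in gene_tree.preorder() if v.id not in locus_map]
    if missing:
        raise CoverageError("locus map is not total on the gene tree", missing)
    return sum(
        1
        for v in gene_tree.preorder()
        if not v.is_root and locus_map[v.id] != locus_map[v.parent.id]
    )


def loss_events(
    instance: ReconInstance, lct: LCT, *, validate: bool = True
) -> Dict[str, int]:
    """Losses per species edge (keyed by the edge's child node).

    A locus is lost on e(s) when it appears among the loci at the top of the
    branch or on nodes within it, but not among the loci at its bottom.
    Distinct loci are counted independently on the same edge.
    """
    if validate:
        violations = validate_lct(instance, lct)
        if violations:
            raise ValidationError(violations)
    S = instance.species_tree
    by_species: Dict[str, List[str]] = defaultdict(list)
    for v in lct.gene_tree.preorder():
        by_species[lct.species_map[v.id]].append(v.id)
    gene_nodes = lct.gene_tree.nodes

    def loci_of(ids) -> Set:
        return {lct.locus_map[g] for g in ids}

    bottoms_cache: Dict[str, Set[str]] = {}
    for s, members in by_species.items():
        bs = set()
        for gid in members:
            g = gene_nodes[gid]
            if g.is_leaf or all(lct.species_map[c.id] != s for c in g.children):
                bs.add(gid)
        bottoms_cache[s] = bs

    out: Dict[str, int] = {}
    for s in S.edges():
        p = S.parent_id(s)
        top_ids = bottoms_cache.get(p, set())
        within = by_species.get(s, [])
        lost = (loci_of(top_ids) | loci_of(within)) - loci_of(bottoms_cache.get(s, set()))
        if lost:
            out[s] = len(lost)
    return out


def count_losses(instance: ReconInstance, lct: LCT, *, validate: bool = True) -> int:
    return sum(loss_events(instance, lct, validate=validate).values())


def reconciliation_cost(
    instance: ReconInstance, lct: LCT, *, validate: bool = True
) -> EventCount:
    """Total cost ``d * cost_dup + l * cost_loss``.  Integer costs stay
    integral (no floating point is introduced)."""
    losses = count_losses(instance, lct, validate=validate)
    dups = count_duplications(lct.gene_tree, lct.locus_map)
    return EventCount(
        duplications=dups,
        losses=losses,
        cost=dups * instance.cost_dup + losses * instance.cost_loss,
    )


# -- LCT validation ------------------------------------------------------


def validate_lct(instance: ReconInstance, lct: LCT) -> List[Violation]:
    """Check all five LCT constraints; return one record per violation.

    The maps must be total on ``lct.gene_tree`` (the augmented gene tree);
    partial maps raise :class:`CoverageError`.
    """
    T = lct.gene_tree
    missing = [v.id for v in T.preorder() if v.id not in lct.species_map.mapping]
    if missing:
        raise CoverageError("species map is not total on the gene tree", missing)
    missing = [v.id for v in T.preorder() if v.id not in lct.locus_map]
    if missing:
        raise CoverageError("locus map is not total on the gene tree", missing)
    stray = sorted(
        {str(lct.locus_map[v.id]) for v in T.preorder()}
        - {str(l) for l in lct.locus_set}
    )
    if stray:
        raise CoverageError(f"locus map uses loci {stray} outside the locus set", stray)

    out: List[Violation] = []
    out.extend(
        validate_species_map(T, instance.species_tree, instance.leaf_map, lct.species_map)
    )

    # constraint 3: paralogous leaves carry distinct loci
    by_image: Dict[str, List[str]] = defaultdict(list)
    for leaf in T.leaves():
        by_image[instance.leaf_map[leaf]].append(leaf)
    for image, group in sorted(by_image.items()):
        for a in range(len(group)):
            for b in range(a + 1, len(group)):
                g, g2 = group[a], group[b]
                if lct.locus_map[g] == lct.locus_map[g2]:
                    out.append(
                        Violation(
                            3,
                            (g, g2),
                            f"paralogous leaves {g},{g2} (species {image}) share "
                            f"locus {lct.locus_map[g]}",
                        )
                    )

    # constraint 4: no unused loci
    used = {lct.locus_map[v.id] for v in T.preorder()}
    for locus in sorted(lct.locus_set - used, key=str):
        out.append(Violation(4, (locus,), f"locus {locus} is unused"))

    # constraint 5: one creation node per locus, none for the root's locus
    creations: Dict[object, List[str]] = defaultdict(list)
    for v in T.preorder():
        if not v.is_root and lct.locus_map[v.id] != lct.locus_map[v.parent.id]:
            creations[lct.locus_map[v.id]].append(v.id)
    root_locus = lct.locus_map[T.root.id]
    for locus in sorted(used, key=str):
        n_created = len(creations.get(locus, []))
        expected = 0 if locus == root_locus else 1
        if n_created != expected:
            out.append(
                Violation(
                    5,
                    (locus,) + tuple(creations.get(locus, [])),
                    f"locus {locus} has {n_created} creation node(s), "
                    f"expected {expected}",
                )
            )
    return out


# -- duplication placements (locus-map equivalence) ----------------------


def placement_from_locus_map(
    gene_tree: RootedBinaryTree, locus_map: Mapping
) -> DuplicationPlacement:
    """The edges on which the locus changes; its size equals the duplication
    count."""
    missing = [v.id for v in gene_tree.preorder() if v.id not in locus_map]
    if missing:
        raise CoverageError("locus map is not total on the gene tree", missing)
    edges = frozenset(
        v.id
        for v in gene_tree.preorder()
        if not v.is_root and locus_map[v.id] != locus_map[v.parent.id]
    )
    return DuplicationPlacement(edges)


def locus_map_from_placement(
    gene_tree: RootedBinaryTree, placement: DuplicationPlacement
) -> Tuple[FrozenSet[int], Dict[str, int]]:
    """Loci are the connected components of the gene tree with the placement
    edges removed, numbered by preorder discovery (the root's component is
    0).  Induces exactly ``len(placement)`` duplications and satisfies
    constraints 4-5 by construction."""
    for e in placement.edges:
        v = gene_tree.node(e)
        if v.is_root:
            raise UnknownNodeError(f"{e!r} is the root; it has no edge")
    locus_map: Dict[str, int] = {}
    next_locus = 0
    for v in gene_tree.preorder():
        if v.is_root or v.id in placement.edges:
            locus_map[v.id] = next_locus
            next_locus += 1
        else:
            locus_map[v.id] = locus_map[v.parent.id]
    return frozenset(range(next_locus)), locus_map


def paralogous_leaf_pairs(instance: ReconInstance) -> List[Tuple[str, str]]:
    """All unordered gene-leaf pairs with equal leaf-map image, each once,
    lexicographically sorted."""
    by_image: Dict[str, List[str]] = defaultdict(list)
    for leaf in instance.gene_tree.leaves():
        by_image[instance.leaf_map[leaf]].append(leaf)
    pairs: List[Tuple[str, str]] = []
    for group in by_image.values():
        group = sorted(group)
        for a in range(len(group)):
            for b in range(a + 1, len(group)):
                pairs.append((group[a], group[b]))
    return sorted(pairs)


def is_duplication_placement(
    instance: ReconInstance, placement: DuplicationPlacement
) -> bool:
    """True iff every paralogous leaf pair is separated by some placement
    edge (vacuously true with no paralogs)."""
    G = instance.gene_tree
    for g, g2 in paralogous_leaf_pairs(instance):
        if not placement.edges.intersection(G.path_edges(g, g2)):
            return False
    return True


# -- public scoring entry point ------------------------------------------


def score_placement(
    instance: ReconInstance,
    species_map: Optional[SpeciesMap] = None,
    placement: DuplicationPlacement = EMPTY_PLACEMENT,
    *,
    check: bool = True,
) -> Tuple[LCT, EventCount]:
    """Score a reconciliation given a species map and a duplication placement.

    Enforces the stipulated ordering: the species map is fixed on the input
    gene tree, implied speciation nodes are inserted, and the locus map is
    then derived from the placement on the augmented tree.  Placement edges
    may name augmented-tree edges (duplications on edges entering implied
    speciation nodes are permitted).  Defaults: the lca species map and the
    empty placement.
    """
    if species_map is None:
        species_map = lca_species_map(instance)
    aug, extended = add_implied_speciations(
        instance.gene_tree, instance.species_tree, species_map
    )
    locus_set, locus_map = locus_map_from_placement(aug, placement)
    lct = LCT(aug, extended, locus_set, locus_map)
    if check:
        violations = validate_lct(instance, lct)
        if violations:
            raise ValidationError(violations)
    return lct, reconciliation_cost(instance, lct, validate=False)
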