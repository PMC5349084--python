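"""Shared fixtures and independent oracles.

The oracles here are deliberately coded from first principles (root-path
intersections, per-edge subdivision, exhaustive subset search, truth
tables) so that the implementation under test never checks itself.
"""

from __future__ import annotations

import itertools
import random
from typing import Dict, List, Optional, Set, Tuple

import pytest

from dlcrecon.model import (
    LeafMap,
    ReconInstance,
    SpeciesMap,
)
from dlcrecon.trees import RootedBinaryTree, TreeNode


# -- oracles over trees --------------------------------------------------


def root_path_ids(tree: RootedBinaryTree, node_id: str) -> List[str]:
    path = []
    v = tree.node(node_id)
    while v is not None:
        path.append(v.id)
        v = v.parent
    return path[::-1]


def lca_oracle(tree: RootedBinaryTree, u: str, v: str) -> str:
    """Intersect root paths, take the deepest common node."""
    pu, pv = root_path_ids(tree, u), root_path_ids(tree, v)
    common = None
    for a, b in zip(pu, pv):
        if a == b:
            common = a
        else:
            break
    return common


def separating_edges_oracle(tree: RootedBinaryTree, u: str, v: str) -> Set[str]:
    """Edges separating u and v = symmetric difference of root-path edge
    sets (an edge is named by its child, so a root path contributes every
    node on it except the root)."""
    eu = set(root_path_ids(tree, u)[1:])
    ev = set(root_path_ids(tree, v)[1:])
    return eu ^ ev


def implied_speciation_oracle(
    gene_tree: RootedBinaryTree,
    species_tree: RootedBinaryTree,
    species_map: SpeciesMap,
) -> Tuple[RootedBinaryTree, Dict[str, str]]:
    """Direct per-edge construction of the canonical augmentation: each
    gene edge (u, v) is subdivided by one node per species node on the
    strict path between M(u) and M(v), plus one at M(u) itself when u is
    not a speciation node (some child of u stays in u's species)."""
    M = dict(species_map.mapping)
    T = gene_tree.copy()
    non_spec = {
        v.id: any(M[c.id] == M[v.id] for c in v.children)
        for v in gene_tree.preorder()
        if not v.is_leaf
    }
    for v in gene_tree.preorder():
        if v.is_root:
            continue
        lower, upper = M[v.id], M[v.parent.id]
        if lower == upper:
            continue
        chain = []  # species strictly between upper and lower, bottom-up
        cur = species_tree.parent_id(lower)
        while cur != upper:
            chain.append(cur)
            cur = species_tree.parent_id(cur)
        if non_spec[v.parent.id]:
            chain.append(upper)
        child = v.id
        for s in chain:  # insert bottom-up, each above the previous
            hid = f"{v.id}@{s}"
            T.subdivide_edge(child, hid)
            M[hid] = s
            child = hid
    return T, M


# -- exhaustive search oracles -------------------------------------------


def min_multicut_oracle(
    tree: RootedBinaryTree, pairs: List[Tuple[str, str]]
) -> int:
    """Minimum multicut size by exhaustive subset search in ascending size."""
    paths = [set(tree.path_edges(*p)) for p in pairs]
    edges = sorted(tree.edges())
    for size in range(len(pairs) + 1):
        for combo in itertools.combinations(edges, size):
            if all(set(combo) & p for p in paths):
                return size
    return len(pairs)


def satisfiable_oracle(clauses, num_vars: int) -> bool:
    """Truth-table satisfiability for tiny formulas."""
    for bits in itertools.product((False, True), repeat=num_vars):
        val = {i + 1: b for i, b in enumerate(bits)}
        if all(
            any((val[abs(l)] if l > 0 else not val[abs(l)]) for l in clause)
            for clause in clauses
        ):
            return True
    return False


# -- random generation helpers -------------------------------------------


def random_valid_species_map(
    instance: ReconInstance, rng: random.Random
) -> SpeciesMap:
    """A uniform-ish random species map satisfying constraints 1-2: each
    internal node picks uniformly from the species path between its
    children's lca image and its parent's image."""
    G, S = instance.gene_tree, instance.species_tree
    lca_img: Dict[str, str] = {}
    for v in G.postorder():
        if v.is_leaf:
            lca_img[v.id] = instance.leaf_map[v.id]
        else:
            img = lca_img[v.children[0].id]
            for c in v.children[1:]:
                img = S.lca(img, lca_img[c.id])
            lca_img[v.id] = img
    mapping: Dict[str, str] = {l: instance.leaf_map[l] for l in G.leaves()}
    for v in G.preorder():
        if v.is_leaf:
            continue
        upper = mapping[v.parent.id] if v.parent is not None else None
        seg = [lca_img[v.id]]
        cur = lca_img[v.id]
        while cur != upper:
            cur = S.parent_id(cur)
            if cur is None:
                break
            seg.append(cur)
        mapping[v.id] = rng.choice(seg)
    return SpeciesMap(mapping)


def random_placement(
    tree: RootedBinaryTree, rng: random.Random, max_size: Optional[int] = None
):
    """A random subset of edges (not necessarily a valid placement)."""
    edges = tree.edges()
    if not edges:
        return frozenset()
    k = rng.randint(0, max_size if max_size is not None else len(edges))
    return frozenset(rng.sample(edges, min(k, len(edges))))


@pytest.fixture
def rng():
    return random.Random(20170314)
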