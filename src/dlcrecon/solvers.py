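"""Exact desk-scale optimization and minimum-duplication (multicut) solvers.

Minimizing duplications alone is exactly minimum multicut on the gene tree
with the paralogous leaf pairs as terminal pairs (placement equivalence:
duplication placements are edge multicuts).  This module provides:

* :func:`min_dup_exact` -- branch-and-bound exact minimum multicut, with an
  admissible lower bound from greedy edge-disjoint uncovered paths;
* :func:`min_dup_approx` -- the classical primal-dual factor-2 multicut
  algorithm for trees (bottom-up dual raising plus reverse delete);
* :func:`solve_dlcop` / :func:`solve_dlcdp` -- exact optimization/decision
  for the full duplication+loss objective by enumerating species maps and
  duplication placements on the augmented gene tree, with a provably exact
  fast path when losses cost 0.

All solvers are deterministic: ties break lexicographically on node ids.
Desk-scale guards raise :class:`~dlcrecon.errors.SizeError` rather than
silently truncating the search.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from .errors import ConfigError, SizeError
from .model import (
    LCT,
    DuplicationPlacement,
    EventCount,
    ReconInstance,
    SpeciesMap,
    add_implied_speciations,
    count_duplications,
    count_losses,
    lca_species_map,
    locus_map_from_placement,
    paralogous_leaf_pairs,
    reconciliation_cost,
    score_placement,
)
from .trees import RootedBinaryTree


@dataclass
class SolverResult:
    best_lct: LCT
    best_placement: DuplicationPlacement
    events: EventCount
    optimal: bool
    explored: int
    cap: Optional[int] = None


def paralog_pairs(instance: ReconInstance) -> List[Tuple[str, str]]:
    """Unordered gene-leaf pairs with equal leaf-map image (the multicut
    terminal pairs)."""
    return paralogous_leaf_pairs(instance)


def _pair_paths(
    tree: RootedBinaryTree,
    pairs: Sequence[Tuple[str, str]],
    *,
    exclude_terminal: bool = False,
) -> List[Tuple[Tuple[str, str], Tuple[str, ...]]]:
    terminal = set(tree.terminal_edges()) if exclude_terminal else set()
    out = []
    for pair in pairs:
        path = [e for e in tree.path_edges(*pair) if e not in terminal]
        if not path:
            raise ConfigError(
                f"pair {pair} has no candidate separating edge"
                + (" with terminal edges excluded" if exclude_terminal else "")
            )
        out.append((pair, tuple(sorted(path))))
    # short paths first: stronger early constraints
    out.sort(key=lambda item: (len(item[1]), item[0]))
    return out


def _greedy_disjoint_lower_bound(
    paths: Sequence[FrozenSet[str]],
) -> int:
    """Admissible lower bound: a set of pairwise edge-disjoint uncovered
    paths, each of which needs its own cut edge."""
    used: Set[str] = set()
    count = 0
    for path in paths:
        if not (path & used):
            count += 1
            used |= path
    return count


def _lp_lower_bound(
    paths: Sequence[FrozenSet[str]],
    open_indices: Sequence[int],
    banned: Set[str],
) -> int:
    """Fractional-multicut LP relaxation, rounded up: an admissible lower
    bound on the number of additional edges needed to cover the open pairs
    without the already-rejected edges."""
    import numpy as np
    from scipy.optimize import linprog
    from scipy.sparse import lil_matrix

    edges = sorted({e for i in open_indices for e in paths[i]} - banned)
    if not edges:
        return len(open_indices) + 1  # some pair has no edge left: infeasible
    index = {e: col for col, e in enumerate(edges)}
    A = lil_matrix((len(open_indices), len(edges)))
    for row, i in enumerate(open_indices):
        usable = [e for e in paths[i] if e not in banned]
        if not usable:
            return len(open_indices) + 1
        for e in usable:
            A[row, index[e]] = -1.0
    res = linprog(
        np.ones(len(edges)),
        A_ub=A.tocsr(),
        b_ub=-np.ones(len(open_indices)),
        bounds=(0, 1),
        method="highs",
    )
    if not res.success:  # pragma: no cover - defensive
        return 0
    return math.ceil(res.fun - 1e-9)


def _min_multicut(
    pair_paths: Sequence[Tuple[Tuple[str, str], Tuple[str, ...]]],
    *,
    budget: Optional[int] = None,
) -> Tuple[Optional[FrozenSet[str]], bool, int]:
    """Branch and bound on uncovered pairs.

    The admissible lower bound is the maximum of a greedy edge-disjoint
    path packing and (when the cheap bound does not already prune) the
    fractional-multicut LP relaxation rounded up.  Returns ``(best_cut,
    proven_optimal, explored)``.  With ``budget`` set, the search
    short-circuits at the first cut of size <= budget (and proves none
    exists otherwise); the returned cut is then feasible but not
    necessarily minimum.
    """
    paths = [frozenset(p) for _, p in pair_paths]
    ordered = [p for _, p in pair_paths]
    n_pairs = len(paths)
    explored = 0

    best: Optional[Tuple[str, ...]] = None
    best_size = n_pairs + 1  # one edge per pair always suffices
    if budget is not None:
        best_size = min(best_size, budget + 1)

    chosen: List[str] = []
    chosen_set: Set[str] = set()

    def uncovered() -> List[int]:
        return [i for i in range(n_pairs) if not (paths[i] & chosen_set)]

    found_budget = False

    def recurse() -> bool:
        """Returns True to abort the whole search (budget satisfied)."""
        nonlocal best, best_size, explored, found_budget
        explored += 1
        open_pairs = uncovered()
        if not open_pairs:
            if len(chosen) < best_size:
                best = tuple(sorted(chosen))
                best_size = len(chosen)
                if budget is not None and best_size <= budget:
                    found_budget = True
                    return True
            return False
        lb = _greedy_disjoint_lower_bound([paths[i] for i in open_pairs])
        if len(chosen) + lb >= best_size:
            return False
        if len(open_pairs) >= 8:
            lb = max(lb, _lp_lower_bound(paths, open_pairs, set()))
            if len(chosen) + lb >= best_size:
                return False
        branch = open_pairs[0]
        for edge in ordered[branch]:
            chosen.append(edge)
            chosen_set.add(edge)
            abort = recurse()
            chosen.pop()
            chosen_set.remove(edge)
            if abort:
                return True
        return False

    recurse()
    if best is None:
        # exhaustive search proved no cut within budget exists
        return None, True, explored
    # with a budget the search stops at the first feasible cut, which need
    # not be minimum; without one the search space was exhausted
    return frozenset(best), budget is None, explored


def min_dup_exact(
    instance: ReconInstance,
    *,
    max_edges: int = 40,
    exclude_terminal: bool = False,
) -> SolverResult:
    """Minimum-cardinality duplication placement by branch and bound.

    ``exclude_terminal`` restricts the search to non-terminal edges (any
    cover using a terminal edge can be pushed up one level without changing
    the optimum when losses cost 0); it is rejected when the instance prices
    losses.
    """
    G = instance.gene_tree
    n_edges = len(G.edges())
    if n_edges > max_edges:
        raise SizeError(
            f"gene tree has {n_edges} edges > guard {max_edges}; "
            "raise max_edges or use min_dup_approx"
        )
    if exclude_terminal and instance.cost_loss != 0:
        raise ConfigError(
            "excluding terminal edges is only optimum-preserving when the "
            "loss cost is 0"
        )
    pairs = paralog_pairs(instance)
    pair_paths = _pair_paths(G, pairs, exclude_terminal=exclude_terminal)
    cut, proven, explored = _min_multicut(pair_paths)
    placement = DuplicationPlacement(cut if cut is not None else frozenset())
    lct, events = score_placement(instance, None, placement)
    return SolverResult(lct, placement, events, optimal=True, explored=explored)


def min_dup_approx(instance: ReconInstance) -> SolverResult:
    """Primal-dual factor-2 multicut on trees with reverse delete.

    Internal nodes are processed bottom-up; each still-connected terminal
    pair whose lca is the current node raises its dual until some path edge
    goes tight; tight edges enter the cut.  A final reverse-delete pass
    removes redundant edges.  The output is always a valid duplication
    placement of size at most twice the minimum.
    """
    G = instance.gene_tree
    pairs = paralog_pairs(instance)
    if not pairs:
        lct, events = score_placement(instance, None, DuplicationPlacement(frozenset()))
        return SolverResult(
            lct, DuplicationPlacement(frozenset()), events, optimal=False, explored=0
        )
    paths = {pair: G.path_edges(*pair) for pair in pairs}
    by_lca: Dict[str, List[Tuple[str, str]]] = {}
    for pair in pairs:
        by_lca.setdefault(G.lca(*pair), []).append(pair)

    slack: Dict[str, Fraction] = {e: Fraction(1) for e in G.edges()}
    cut: List[str] = []
    cut_set: Set[str] = set()
    order = sorted(by_lca, key=lambda v: (-G.depth(v), v))
    for v in order:
        for pair in sorted(by_lca[v]):
            path = paths[pair]
            if cut_set.intersection(path):
                continue
            raise_by = min(slack[e] for e in path)
            for e in path:
                slack[e] -= raise_by
            for e in path:  # deterministic: path order, u-leg then v-leg
                if slack[e] == 0 and e not in cut_set:
                    cut.append(e)
                    cut_set.add(e)
    # reverse delete
    for e in reversed(list(cut)):
        reduced = cut_set - {e}
        if all(reduced.intersection(paths[p]) for p in pairs):
            cut_set = reduced
    placement = DuplicationPlacement(frozenset(cut_set))
    lct, events = score_placement(instance, None, placement)
    return SolverResult(lct, placement, events, optimal=False, explored=len(order))


# -- species-map enumeration and full optimization ------------------------


def enumerate_species_maps(instance: ReconInstance):
    """Yield every species map satisfying constraints 1-2, each exactly once.

    Each internal node's image ranges over the species-tree path between the
    lca of its descendant leaves' images (inclusive, lower end) and its
    parent's image (inclusive, upper end); the root ranges up to the species
    root.  Yield order is deterministic (preorder nodes, images deep-to-shallow).
    """
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

    internal = [v for v in G.preorder() if not v.is_leaf]
    leaves = {l: instance.leaf_map[l] for l in G.leaves()}
    if not internal:
        yield SpeciesMap(dict(leaves))
        return

    def segment(lower: str, upper: Optional[str]) -> List[str]:
        """Species nodes from ``lower`` up to ``upper`` (root if None)."""
        out = [lower]
        cur = lower
        while cur != upper:
            cur = S.parent_id(cur)
            if cur is None:
                break
            out.append(cur)
        return out

    assignment: Dict[str, str] = dict(leaves)

    def rec(i: int):
        if i == len(internal):
            yield SpeciesMap(dict(assignment))
            return
        g = internal[i]
        upper = assignment[g.parent.id] if g.parent is not None else None
        for s in segment(lca_img[g.id], upper):
            assignment[g.id] = s
            yield from rec(i + 1)
        del assignment[g.id]

    yield from rec(0)


def _covers_all(placement: FrozenSet[str], paths: Sequence[FrozenSet[str]]) -> bool:
    return all(placement & p for p in paths)


def solve_dlcop(
    instance: ReconInstance,
    *,
    max_edges: int = 12,
    max_species_maps: int = 5000,
    slack: int = 1,
    stop_at: Optional[float] = None,
    mindup_max_edges: int = 40,
) -> SolverResult:
    """Exact minimum-cost reconciliation (DLC optimization problem).

    When the loss cost is 0 the optimum collapses to the minimum multicut
    (duplications depend only on the locus map and any valid species map
    will do), so the exact multicut solver is used directly.  Otherwise the
    solver enumerates every constraint-1/2 species map, augments the gene
    tree, and enumerates duplication placements over the augmented edges up
    to ``#paralog pairs + slack`` edges (no optimum needs more duplications
    than pairs when losses are priced non-negatively; the cap is recorded in
    the result for audit).  ``stop_at`` short-circuits as soon as a
    candidate at or below that cost is found (used by the decision problem).
    """
    pairs = paralog_pairs(instance)

    if instance.cost_loss == 0:
        res = min_dup_exact(instance, max_edges=mindup_max_edges)
        return res

    n_edges = len(instance.gene_tree.edges())
    if n_edges > max_edges:
        raise SizeError(
            f"gene tree has {n_edges} edges > guard {max_edges} for full "
            "species-map enumeration; raise max_edges"
        )
    cap = len(pairs) + slack

    best: Optional[Tuple[LCT, DuplicationPlacement, EventCount]] = None
    explored = 0
    n_maps = 0
    for species_map in enumerate_species_maps(instance):
        n_maps += 1
        if n_maps > max_species_maps:
            raise SizeError(
                f"more than {max_species_maps} species maps; raise max_species_maps"
            )
        aug, extended = add_implied_speciations(
            instance.gene_tree, instance.species_tree, species_map
        )
        aug_edges = sorted(aug.edges())
        pair_paths = [frozenset(aug.path_edges(*p)) for p in pairs]
        for size in range(0, min(cap, len(aug_edges)) + 1):
            if best is not None and size * instance.cost_dup > best[2].cost:
                break
            for combo in itertools.combinations(aug_edges, size):
                pl = frozenset(combo)
                if not _covers_all(pl, pair_paths):
                    continue
                explored += 1
                placement = DuplicationPlacement(pl)
                locus_set, locus_map = locus_map_from_placement(aug, placement)
                lct = LCT(aug, extended, locus_set, locus_map)
                events = reconciliation_cost(instance, lct, validate=False)
                if best is None or events.cost < best[2].cost:
                    best = (lct, placement, events)
                    if stop_at is not None and events.cost <= stop_at:
                        return SolverResult(
                            lct, placement, events, optimal=False,
                            explored=explored, cap=cap,
                        )
    assert best is not None, "species-map enumeration yielded nothing"
    return SolverResult(
        best[0], best[1], best[2], optimal=True, explored=explored, cap=cap
    )


def solve_dlcdp(
    instance: ReconInstance,
    k: float,
    *,
    max_edges: int = 12,
    max_species_maps: int = 5000,
    slack: int = 1,
    mindup_max_edges: int = 200,
    exclude_terminal: bool = False,
) -> bool:
    """Decision problem: does a reconciliation of cost at most ``k`` exist?

    Short-circuits as soon as a candidate at or below ``k`` is found.  With
    zero loss cost the question reduces to a budgeted multicut search;
    ``exclude_terminal`` then restricts the search to non-terminal edges
    (duplications on terminal edges can always be pushed up one level when
    losses are free, so the answer is unchanged).
    """
    if k < 0:
        raise ConfigError("decision parameter k must be non-negative")
    if exclude_terminal and instance.cost_loss != 0:
        raise ConfigError(
            "excluding terminal edges is only answer-preserving when the "
            "loss cost is 0"
        )
    if instance.cost_loss == 0:
        if instance.cost_dup == 0:
            return True  # every reconciliation costs 0
        budget = math.floor(k / instance.cost_dup)
        G = instance.gene_tree
        if len(G.edges()) > mindup_max_edges:
            raise SizeError(
                f"gene tree has {len(G.edges())} edges > guard {mindup_max_edges}"
            )
        pairs = paralog_pairs(instance)
        pair_paths = (
            _pair_paths(G, pairs, exclude_terminal=exclude_terminal)
            if pairs
            else []
        )
        if not pair_paths:
            return True
        cut, _, _ = _min_multicut(pair_paths, budget=budget)
        return cut is not None
    result = solve_dlcop(
        instance,
        max_edges=max_edges,
        max_species_maps=max_species_maps,
        slack=slack,
        stop_at=k,
    )
    return result.events.cost <= k
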