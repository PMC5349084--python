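"""Deterministic generators for trees, reconciliation instances and
formulas, plus the worked single-clause example.

The cost model here is purely combinatorial, so the generators produce
structural randomness only (tree shapes, leaf-map collisions, clause
draws); no birth-death or coalescent process is emulated.  Every generator
is a pure function of its arguments: the same seed always yields the same
object, bit for bit.
"""

from __future__ import annotations

import random
from typing import Optional, Tuple

from .errors import ConfigError, SizeError
from .model import LeafMap, ReconInstance
from .reductions import CNFFormula, DLCDPInstance, build_np_instance
from .trees import RootedBinaryTree, TreeNode


def random_tree(
    n_leaves: int,
    seed: int,
    *,
    leaf_prefix: str = "L",
    internal_prefix: str = "v",
) -> RootedBinaryTree:
    """A random binary tree shape over ``n_leaves`` labeled leaves, built by
    recursive uniform splits of the leaf sequence."""
    if n_leaves < 1:
        raise SizeError(f"need at least 1 leaf, got {n_leaves}")
    rng = random.Random(seed)
    counter = [0]

    def build(lo: int, hi: int) -> TreeNode:
        if hi - lo == 1:
            return TreeNode(f"{leaf_prefix}{lo + 1}")
        split = rng.randint(lo + 1, hi - 1)
        counter[0] += 1
        return TreeNode(
            f"{internal_prefix}{counter[0]}", [build(lo, split), build(split, hi)]
        )

    return RootedBinaryTree(build(0, n_leaves))


def random_instance(
    n_gene_leaves: int,
    n_species_leaves: int,
    paralogy_rate: float,
    seed: int,
    *,
    cost_dup: float = 1,
    cost_loss: float = 0,
) -> ReconInstance:
    """A random reconciliation instance.

    Each gene leaf, in order, joins an already-used species leaf with
    probability ``paralogy_rate`` (creating paralogs) and otherwise takes a
    fresh unused species leaf; when the preferred option is unavailable the
    other is used.  The species topology is drawn independently of the leaf
    map (the cost model imposes no compatibility constraint).
    """
    if n_gene_leaves < 1 or n_species_leaves < 1:
        raise ConfigError("leaf counts must be at least 1")
    if not 0 <= paralogy_rate <= 1:
        raise ConfigError("paralogy_rate must lie in [0, 1]")
    rng = random.Random(seed)
    gene = random_tree(n_gene_leaves, rng.randrange(2**31), leaf_prefix="g")
    species = random_tree(n_species_leaves, rng.randrange(2**31), leaf_prefix="s")
    species_leaves = species.leaves()
    used: list[str] = []
    fresh = list(species_leaves)
    mapping = {}
    for leaf in gene.leaves():
        join = rng.random() < paralogy_rate
        if join and used:
            mapping[leaf] = rng.choice(used)
        elif fresh:
            target = fresh.pop(rng.randrange(len(fresh)))
            used.append(target)
            mapping[leaf] = target
        elif used:
            mapping[leaf] = rng.choice(used)
        else:  # pragma: no cover - unreachable with counts >= 1
            raise ConfigError("no species leaf available")
    return ReconInstance(
        gene, species, LeafMap(mapping), cost_dup=cost_dup, cost_loss=cost_loss
    )


def random_cnf(m: int, n: int, B: int, seed: int) -> CNFFormula:
    """A random normalized 3-CNF formula with ``m`` variables, ``n``
    clauses, and every variable occurring at least once and at most ``B``
    times.  Requires ``3 <= m <= 3n`` (so all variables can occur) and
    ``3n <= m * B`` (so the occurrence bound is feasible)."""
    if m < 3:
        raise ConfigError("need at least 3 variables for 3-literal clauses")
    if n < 1:
        raise ConfigError("need at least 1 clause")
    if 3 * n > m * B:
        raise ConfigError(f"infeasible: 3n={3 * n} slots exceed m*B={m * B}")
    if m > 3 * n:
        raise ConfigError(
            f"infeasible: {m} variables cannot all occur in {3 * n} literal slots"
        )
    rng = random.Random(seed)

    def attempt() -> Optional[CNFFormula]:
        counts = {i: 0 for i in range(1, m + 1)}
        clauses = []
        for j in range(n):
            remaining_clauses = n - j - 1
            chosen: list[int] = []
            for _ in range(3):
                open_vars = [i for i in counts if counts[i] < B and i not in chosen]
                if not open_vars:
                    return None  # a draw painted itself into a corner; retry
                unused = [i for i in open_vars if counts[i] == 0]
                # force not-yet-used variables in when slots get scarce
                slots_left = 3 * remaining_clauses + (3 - len(chosen) - 1)
                pool = unused if unused and len(unused) > slots_left else open_vars
                chosen.append(rng.choice(pool))
            clause = tuple(v if rng.random() < 0.5 else -v for v in sorted(chosen))
            for v in chosen:
                counts[v] += 1
            clauses.append(clause)
        return CNFFormula(num_vars=m, clauses=tuple(clauses))

    for _ in range(100):
        formula = attempt()
        if formula is not None:
            formula.check_normalized()
            return formula
    raise ConfigError("could not draw a formula within the occurrence bound")


def single_clause_example() -> Tuple[CNFFormula, DLCDPInstance]:
    """The worked single-clause decision instance for (x1 v -x2 v x3):
    m = 3, n = 1, decision parameter 5."""
    formula = CNFFormula(num_vars=3, clauses=((1, -2, 3),))
    return formula, build_np_instance(formula)
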