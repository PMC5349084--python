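"""Compilers from Boolean formulas to DLC reconciliation instances.

Two constructive reductions are implemented:

* :func:`build_np_instance` compiles a 3-CNF formula into a decision
  instance (duplication cost 1, loss cost 0, decision parameter
  ``2n + m``): the formula is satisfiable iff the instance admits a
  reconciliation with at most ``2n + m`` duplications.  Variable gadgets
  force one duplication on a chosen true/false branch; clause gadgets force
  two duplications, leaving one literal branch free -- which must then be
  "paid for" by the matching variable branch.

* :func:`build_apx_instance` compiles a MAX3SAT(B) formula (each variable
  occurring at most B times) into an optimization instance with duplication
  cost ``2Bn^2`` and loss cost 1.  Thorn gadgets (caterpillars with a
  designated end tip) amplify the loss count so that every satisfied clause
  contributes exactly ``2n^2`` thorn losses and every unsatisfied clause
  ``3n^2``, separating satisfiable formulas (cost below
  ``b = (10B+2)n^3 + 121n^2``) from barely-satisfiable ones.

Both directions of each correctness argument are implemented as executable
maps between valuations and solutions (``*_solution_from_valuation`` /
``*_valuation_from_solution``), so the reductions can be verified
constructively on concrete instances.

All "arbitrary binary tree" choices are realized as caterpillars with
deterministic labels, so instances are byte-reproducible.  Within each
construction the true/false edge conventions follow the respective
correctness argument; note they are opposite between the two reductions
(NP side: duplication on ``e(beta_i)`` means true; APX side: duplication on
``e(nbeta_i)`` means true).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

from .errors import (
    ConstraintError,
    EmptyFormulaError,
    FormatError,
    InconsistencyError,
    OccurrenceBoundError,
    SizeError,
    UnsatisfiedClauseError,
)
from .model import (
    DuplicationPlacement,
    LeafMap,
    ReconInstance,
    SpeciesMap,
)
from .trees import RootedBinaryTree, TreeNode, node

# -- CNF formulas --------------------------------------------------------


@dataclass(frozen=True)
class CNFFormula:
    """A 3-CNF formula: clauses are ordered triples of signed 1-based
    variable indices (DIMACS convention), each over three distinct
    variables.  Clause order and within-clause literal order are fixed so
    that "the h-th literal of clause j" and "the q-th occurrence of a
    literal" are well defined."""

    num_vars: int
    clauses: Tuple[Tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        for j, clause in enumerate(self.clauses, 1):
            if len(clause) != 3:
                raise FormatError(f"clause {j} has {len(clause)} literals, expected 3")
            vs = [abs(l) for l in clause]
            if len(set(vs)) != 3:
                raise FormatError(f"clause {j} repeats a variable: {clause}")
            for lit in clause:
                if not (1 <= abs(lit) <= self.num_vars):
                    raise FormatError(f"literal {lit} out of range in clause {j}")

    @property
    def m(self) -> int:
        return self.num_vars

    @property
    def n(self) -> int:
        return len(self.clauses)

    def occurrence_counts(self) -> Tuple[Dict[int, int], Dict[int, int]]:
        """(B(i), B-bar(i)): per-variable counts of positive and negative
        occurrences across the clauses."""
        pos = {i: 0 for i in range(1, self.num_vars + 1)}
        neg = {i: 0 for i in range(1, self.num_vars + 1)}
        for clause in self.clauses:
            for lit in clause:
                (pos if lit > 0 else neg)[abs(lit)] += 1
        return pos, neg

    def max_occurrence(self) -> int:
        """The occurrence bound B actually attained: the maximum number of
        times any one variable appears across the clauses."""
        pos, neg = self.occurrence_counts()
        return max(pos[i] + neg[i] for i in pos) if self.num_vars else 0

    def occurrence_index(self) -> Dict[Tuple[int, int], Tuple[int, int]]:
        """Map (clause j, position h) -> (signed literal, q) where q counts
        occurrences of that literal in clause order."""
        counter: Dict[int, int] = {}
        out: Dict[Tuple[int, int], Tuple[int, int]] = {}
        for j, clause in enumerate(self.clauses, 1):
            for h, lit in enumerate(clause, 1):
                counter[lit] = counter.get(lit, 0) + 1
                out[(j, h)] = (lit, counter[lit])
        return out

    def unused_variables(self) -> List[int]:
        used = {abs(l) for clause in self.clauses for l in clause}
        return [i for i in range(1, self.num_vars + 1) if i not in used]

    def check_normalized(self) -> None:
        unused = self.unused_variables()
        if unused:
            raise ConstraintError(
                f"formula is not normalized: variables {unused} occur in no clause"
            )
        if not self.clauses:
            raise EmptyFormulaError("formula has no clauses")

    def satisfied_clauses(self, valuation: "Valuation") -> List[int]:
        out = []
        for j, clause in enumerate(self.clauses, 1):
            if any(valuation.truth(lit) for lit in clause):
                out.append(j)
        return out

    def is_satisfied_by(self, valuation: "Valuation") -> bool:
        return len(self.satisfied_clauses(valuation)) == self.n

    def satisfying_valuations(self) -> List["Valuation"]:
        """Exhaustive truth table; intended as a tiny-instance oracle."""
        if self.num_vars > 20:
            raise SizeError("truth-table enumeration guarded at 20 variables")
        out = []
        for bits in itertools.product((False, True), repeat=self.num_vars):
            val = Valuation({i + 1: b for i, b in enumerate(bits)})
            if self.is_satisfied_by(val):
                out.append(val)
        return out


@dataclass(frozen=True)
class Valuation:
    """A total truth assignment over variables 1..m."""

    assignment: Mapping[int, bool]

    def __getitem__(self, var: int) -> bool:
        return self.assignment[var]

    def truth(self, literal: int) -> bool:
        value = self.assignment[abs(literal)]
        return value if literal > 0 else not value


def parse_dimacs(text: str) -> CNFFormula:
    """Parse and normalize DIMACS CNF with 3-literal clauses.

    Normalization: duplicate literals within a clause are deduplicated (a
    clause left with fewer than 3 literals is a format error); tautological
    clauses (a literal and its negation) are dropped with a warning, since
    every valuation satisfies them; variables occurring in no surviving
    clause are dropped and indices compacted.
    """
    tokens: List[str] = []
    declared = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("c"):
            continue
        if line.startswith("p"):
            parts = line.split()
            if len(parts) != 4 or parts[1] != "cnf":
                raise FormatError(f"bad problem line: {line!r}")
            declared = (int(parts[2]), int(parts[3]))
            continue
        tokens.extend(line.split())
    try:
        ints = [int(t) for t in tokens]
    except ValueError as exc:
        raise FormatError(f"non-integer token in clause data: {exc}") from None

    raw_clauses: List[List[int]] = []
    cur: List[int] = []
    for x in ints:
        if x == 0:
            if cur:
                raw_clauses.append(cur)
                cur = []
        else:
            cur.append(x)
    if cur:
        raw_clauses.append(cur)

    clauses: List[Tuple[int, ...]] = []
    for idx, clause in enumerate(raw_clauses, 1):
        seen: List[int] = []
        for lit in clause:
            if lit not in seen:
                seen.append(lit)
        if any(-lit in seen for lit in seen):
            warnings.warn(
                f"clause {idx} {tuple(clause)} is a tautology; dropped",
                stacklevel=2,
            )
            continue
        if len(seen) != 3:
            raise FormatError(
                f"clause {idx} {tuple(clause)} has {len(seen)} distinct literals "
                "after deduplication, expected 3"
            )
        clauses.append(tuple(seen))
    if not clauses:
        raise EmptyFormulaError("no clauses remain after normalization")

    used = sorted({abs(l) for clause in clauses for l in clause})
    renum = {v: i + 1 for i, v in enumerate(used)}
    remapped = tuple(
        tuple((1 if l > 0 else -1) * renum[abs(l)] for l in clause)
        for clause in clauses
    )
    return CNFFormula(num_vars=len(used), clauses=remapped)


def write_dimacs(formula: CNFFormula) -> str:
    lines = [f"p cnf {formula.num_vars} {formula.n}"]
    for clause in formula.clauses:
        lines.append(" ".join(str(l) for l in clause) + " 0")
    return "\n".join(lines) + "\n"


# -- shared tree builders ------------------------------------------------


def _caterpillar(items: Sequence[TreeNode], internal_ids: Sequence[str]) -> TreeNode:
    """Left caterpillar: internal node k has children (items[k], next);
    the last internal node holds the final two items."""
    if len(items) == 1:
        return items[0]
    assert len(internal_ids) == len(items) - 1
    cur = node(internal_ids[-1], items[-2], items[-1])
    for k in range(len(items) - 3, -1, -1):
        cur = node(internal_ids[k], items[k], cur)
    return cur


@dataclass
class Thorn:
    """An l-thorn gadget: a caterpillar with internal nodes u_1..u_{l-1}
    and leaves t_1..t_l, where t_l is the designated *end tip* (the unique
    deepest leaf alongside t_{l-1})."""

    tree: RootedBinaryTree
    leaf_ids: Tuple[str, ...]
    end_tip: str


def build_thorn(
    length: int,
    prefix: str = "th",
    *,
    tip_id: Optional[str] = None,
    root_id: Optional[str] = None,
) -> Thorn:
    """Build an ``length``-thorn.  Requires length >= 2."""
    if length < 2:
        raise SizeError(f"a thorn gadget needs at least 2 leaves, got {length}")
    leaf_ids = [f"{prefix}_t{w}" for w in range(1, length + 1)]
    if tip_id is not None:
        leaf_ids[-1] = tip_id
    internal_ids = [f"{prefix}_u{k}" for k in range(1, length)]
    if root_id is not None:
        internal_ids[0] = root_id
    root = _caterpillar([node(l) for l in leaf_ids], internal_ids)
    return Thorn(RootedBinaryTree(root), tuple(leaf_ids), leaf_ids[-1])


# -- NP-hardness reduction ----------------------------------------------


@dataclass
class DLCDPInstance:
    """A compiled decision instance: duplication cost 1, loss cost 0,
    decision parameter ``2n + m``.

    ``gadget_index`` maps semantic keys (``"alpha:i"``, ``"lambda:h,j"``,
    ...) to gene-tree node ids; ``node_gadget`` classifies every gene node
    into its gadget; ``literal_slots`` records, for each (clause, position),
    the signed literal and its occurrence number.
    """

    recon: ReconInstance
    decision_k: int
    formula: CNFFormula
    gadget_index: Dict[str, str]
    node_gadget: Dict[str, Tuple]
    literal_slots: Dict[Tuple[int, int], Tuple[int, int]]


def _np_variable_gadget(i: int, n: int) -> Tuple[TreeNode, Dict[str, str]]:
    index: Dict[str, str] = {}

    def side(bar: bool) -> TreeNode:
        y = "yb" if bar else "y"
        b = "betab" if bar else "beta"
        leaves = [node(f"{y}{i}")] + [node(f"{y}{i}_{k}") for k in range(1, n + 1)]
        internals = [f"{b}{i}"] + [f"{b}{i}_{k}" for k in range(1, n)]
        index[f"{'n' if bar else ''}beta:{i}"] = internals[0]
        index[f"{'n' if bar else ''}y:{i}"] = leaves[0].id
        for k in range(1, n + 1):
            index[f"{'n' if bar else ''}y:{i},{k}"] = leaves[k].id
        return _caterpillar(leaves, internals)

    alpha = node(f"alpha{i}", side(False), side(True))
    index[f"alpha:{i}"] = alpha.id
    return alpha, index


def _np_clause_gadget(j: int) -> Tuple[TreeNode, Dict[str, str]]:
    index: Dict[str, str] = {}
    lams = []
    for h in (1, 2, 3):
        lam = node(f"lam{h}_{j}", node(f"k{h}_{j}"), node(f"kp{h}_{j}"))
        index[f"lambda:{h},{j}"] = lam.id
        index[f"k:{h},{j}"] = f"k{h}_{j}"
        index[f"k':{h},{j}"] = f"kp{h}_{j}"
        lams.append(lam)
    deltap = node(f"deltap{j}", lams[0], lams[1])
    delta = node(f"delta{j}", deltap, lams[2])
    index[f"delta:{j}"] = delta.id
    index[f"delta':{j}"] = deltap.id
    return delta, index


def build_np_instance(formula: CNFFormula) -> DLCDPInstance:
    """Compile a normalized 3-CNF formula into the decision instance.

    Gene tree: a caterpillar backbone whose first m leaves are replaced by
    variable gadgets and remaining n by clause gadgets.  Species tree: a
    caterpillar with ``2mn + m + n`` leaves labeled "1".."2mn+m+n".  The
    leaf map wires paralogous pairs so that any reconciliation with at most
    ``2n + m`` duplications encodes a satisfying valuation.
    """
    formula.check_normalized()
    m, n = formula.m, formula.n
    gadget_index: Dict[str, str] = {}
    node_gadget: Dict[str, Tuple] = {}

    roots: List[TreeNode] = []
    for i in range(1, m + 1):
        sub, idx = _np_variable_gadget(i, n)
        gadget_index.update(idx)
        for v in RootedBinaryTree(sub).preorder():
            node_gadget[v.id] = ("var", i)
        sub.parent = None
        roots.append(sub)
    for j in range(1, n + 1):
        sub, idx = _np_clause_gadget(j)
        gadget_index.update(idx)
        for v in RootedBinaryTree(sub).preorder():
            node_gadget[v.id] = ("clause", j)
        sub.parent = None
        roots.append(sub)
    backbone_ids = [f"bb{t}" for t in range(1, m + n)]
    gene_root = _caterpillar(roots, backbone_ids)
    gene_tree = RootedBinaryTree(gene_root)
    for t in backbone_ids:
        node_gadget[t] = ("backbone",)

    n_species = 2 * m * n + m + n
    species_leaves = [node(str(w)) for w in range(1, n_species + 1)]
    species_root = _caterpillar(
        species_leaves, [f"sp{t}" for t in range(1, n_species)]
    )
    species_tree = RootedBinaryTree(species_root)

    le: Dict[str, str] = {}
    for i in range(1, m + 1):  # part 1
        le[f"y{i}"] = le[f"yb{i}"] = str(i)
    for j in range(1, n + 1):  # part 2
        for h in (1, 2, 3):
            le[f"k{h}_{j}"] = str(m + j)
    slots = formula.occurrence_index()
    for j in range(1, n + 1):  # parts 3-4
        for h in (1, 2, 3):
            lit, _q = slots[(j, h)]
            i = abs(lit)
            partner = f"y{i}_{j}" if lit > 0 else f"yb{i}_{j}"
            le[f"kp{h}_{j}"] = le[partner] = str(m + n + 3 * (j - 1) + h)
    # part 5: remaining gene leaves to unique unused species leaves
    used_species = set(le.values())
    free = [str(w) for w in range(1, n_species + 1) if str(w) not in used_species]
    unmapped = [l for l in gene_tree.leaves() if l not in le]
    assert len(unmapped) == 2 * m * n - 3 * n == len(free)
    for leaf, s in zip(unmapped, free):
        le[leaf] = s

    recon = ReconInstance(
        gene_tree, species_tree, LeafMap(le), cost_dup=1, cost_loss=0
    )
    return DLCDPInstance(
        recon=recon,
        decision_k=2 * n + m,
        formula=formula,
        gadget_index=gadget_index,
        node_gadget=node_gadget,
        literal_slots=slots,
    )


def _chosen_literals(
    formula: CNFFormula, valuation: Valuation
) -> Dict[int, int]:
    """Per clause, the lowest-index position whose literal the valuation
    satisfies; raises for unsatisfied clauses."""
    chosen = {}
    for j, clause in enumerate(formula.clauses, 1):
        sat = [h for h, lit in enumerate(clause, 1) if valuation.truth(lit)]
        if not sat:
            raise UnsatisfiedClauseError(j)
        chosen[j] = min(sat)
    return chosen


def np_solution_from_valuation(
    instance: DLCDPInstance, valuation: Valuation
) -> DuplicationPlacement:
    """The constructive direction: one duplication per variable gadget
    (``e(beta_i)`` when true, ``e(nbeta_i)`` when false) and, per clause,
    duplications on the two literal edges *not* chosen as satisfying.
    Always has size ``2n + m``; it is a valid duplication placement exactly
    when the valuation satisfies the formula."""
    m, n = instance.formula.m, instance.formula.n
    edges: Set[str] = set()
    for i in range(1, m + 1):
        edges.add(f"beta{i}" if valuation[i] else f"betab{i}")
    chosen = _chosen_literals(instance.formula, valuation)
    for j in range(1, n + 1):
        for h in (1, 2, 3):
            if h != chosen[j]:
                edges.add(f"lam{h}_{j}")
    return DuplicationPlacement(frozenset(edges))


def np_valuation_from_solution(
    instance: DLCDPInstance, placement: DuplicationPlacement
) -> Valuation:
    """The extraction direction: x_i is true iff a duplication lies on the
    path from alpha_i to y_i.  For any valid placement within the decision
    budget the resulting valuation satisfies the formula; a gadget with
    duplications on both or neither alpha-path signals an inconsistent
    input."""
    m = instance.formula.m
    assignment: Dict[int, bool] = {}
    for i in range(1, m + 1):
        true_side = {f"beta{i}", f"y{i}"} & placement.edges
        false_side = {f"betab{i}", f"yb{i}"} & placement.edges
        if bool(true_side) == bool(false_side):
            raise InconsistencyError(
                f"variable gadget {i}: duplications on "
                f"{'both' if true_side else 'neither'} of the alpha-to-y paths"
            )
        assignment[i] = bool(true_side)
    return Valuation(assignment)


# -- APX-hardness reduction ----------------------------------------------


@dataclass
class DLCOPInstance:
    """A compiled optimization instance: duplication cost ``2Bn^2``, loss
    cost 1, satisfiability budget ``b = (10B+2)n^3 + 121n^2``.

    ``alpha`` is the gap constant ``epsilon/(20B+4)`` kept symbolic
    (epsilon is an existence constant and carries no numeric value here).
    ``species_thorn_nodes`` maps (h, j) to the node ids of the n^2-thorn
    for that clause position, and ``trunk_nodes`` lists the species trunk,
    enabling per-gadget loss audits.
    """

    recon: ReconInstance
    budget_b: int
    B: int
    alpha: str
    formula: CNFFormula
    gadget_index: Dict[str, str]
    node_gadget: Dict[str, Tuple]
    literal_slots: Dict[Tuple[int, int], Tuple[int, int]]
    occurrence_slot: Dict[Tuple[int, int], Tuple[int, int]]
    species_thorn_nodes: Dict[Tuple[int, int], FrozenSet[str]]
    trunk_nodes: Tuple[str, ...]
    gene_thorn_leaves: Dict[Tuple[int, int], Tuple[str, ...]]


def build_apx_instance(
    formula: CNFFormula, *, occurrence_bound: Optional[int] = None
) -> DLCOPInstance:
    """Compile a normalized MAX3SAT(B) formula into the optimization
    instance.  Requires n >= 2 clauses (the thorn sizes ``n^2 - 1`` and
    ``n^2`` degenerate below that).  ``occurrence_bound`` optionally pins B;
    the formula's attained maximum must not exceed it."""
    formula.check_normalized()
    m, n = formula.m, formula.n
    if n < 2:
        raise SizeError("the construction needs at least 2 clauses")
    attained = formula.max_occurrence()
    if occurrence_bound is not None and attained > occurrence_bound:
        raise OccurrenceBoundError(
            f"a variable occurs {attained} times, above the bound "
            f"{occurrence_bound}"
        )
    B = occurrence_bound if occurrence_bound is not None else attained
    pos_counts, neg_counts = formula.occurrence_counts()
    slots = formula.occurrence_index()
    # (signed literal, q) -> (j, h): where each occurrence sits
    occurrence_slot: Dict[Tuple[int, int], Tuple[int, int]] = {
        (lit, q): jh for jh, (lit, q) in slots.items()
    }

    gadget_index: Dict[str, str] = {}
    node_gadget: Dict[str, Tuple] = {}
    gene_thorn_leaves: Dict[Tuple[int, int], Tuple[str, ...]] = {}
    thorn_len = n * n - 1

    def literal_subtree(i: int, bar: bool) -> TreeNode:
        y = "yb" if bar else "y"
        b = "betab" if bar else "beta"
        count = (neg_counts if bar else pos_counts)[i]
        key = "n" if bar else ""
        y_leaf = node(f"{y}{i}")
        yp_leaf = node(f"{y}p{i}")
        gadget_index[f"{key}y:{i}"] = y_leaf.id
        gadget_index[f"{key}y':{i}"] = yp_leaf.id
        if count == 0:
            # no occurrences of this polarity: the thorn chain is empty and
            # beta'_i collapses to the bare leaf y'_i
            sub = node(f"{b}{i}", y_leaf, yp_leaf)
            gadget_index[f"{key}beta:{i}"] = sub.id
            return sub
        thorns = []
        for q in range(1, count + 1):
            lit = -i if bar else i
            th = build_thorn(
                thorn_len,
                prefix=f"g{'n' if bar else 'p'}th{i}_{q}",
                tip_id=f"{y}{i}_{q}",
            )
            j, h = occurrence_slot[(lit, q)]
            gene_thorn_leaves[(h, j)] = th.leaf_ids
            gadget_index[f"{key}y:{i},{q}"] = th.end_tip
            thorns.append(th.tree.root)
        if count == 1:
            chain = thorns[0]
        else:
            chain = node(f"{b}{i}_{count - 1}", thorns[-2], thorns[-1])
            for q in range(count - 2, 0, -1):
                chain = node(f"{b}{i}_{q}", thorns[q - 1], chain)
        bp = node(f"{b}p{i}", yp_leaf, chain)
        sub = node(f"{b}{i}", y_leaf, bp)
        gadget_index[f"{key}beta:{i}"] = sub.id
        gadget_index[f"{key}beta':{i}"] = bp.id
        return sub

    var_roots: List[TreeNode] = []
    for i in range(1, m + 1):
        alpha_node = node(f"alpha{i}", literal_subtree(i, False), literal_subtree(i, True))
        gadget_index[f"alpha:{i}"] = alpha_node.id
        for v in RootedBinaryTree(alpha_node).preorder():
            node_gadget[v.id] = ("var", i)
        alpha_node.parent = None
        var_roots.append(alpha_node)

    clause_roots: List[TreeNode] = []
    for j in range(1, n + 1):
        lams = []
        for h in (1, 2, 3):
            lamp = node(f"lamp{h}_{j}", node(f"kp{h}_{j}"), node(f"kpp{h}_{j}"))
            lam = node(f"lam{h}_{j}", node(f"k{h}_{j}"), lamp)
            gadget_index[f"lambda:{h},{j}"] = lam.id
            gadget_index[f"lambda':{h},{j}"] = lamp.id
            gadget_index[f"k:{h},{j}"] = f"k{h}_{j}"
            gadget_index[f"k':{h},{j}"] = f"kp{h}_{j}"
            gadget_index[f"k'':{h},{j}"] = f"kpp{h}_{j}"
            lams.append(lam)
        deltap = node(f"deltap{j}", lams[0], lams[1])
        delta = node(f"delta{j}", deltap, lams[2])
        gadget_index[f"delta:{j}"] = delta.id
        gadget_index[f"delta':{j}"] = deltap.id
        for v in RootedBinaryTree(delta).preorder():
            node_gadget[v.id] = ("clause", j)
        delta.parent = None
        clause_roots.append(delta)

    root_thorn_len = 3 * n - m + 1
    if root_thorn_len == 1:
        g1: TreeNode = node("g1")
        g1_leaves: Tuple[str, ...] = ("g1",)
        gadget_index["g1_end_tip"] = "g1"
    else:
        th = build_thorn(root_thorn_len, prefix="g1th", root_id="g1")
        g1 = th.tree.root
        g1.parent = None
        g1_leaves = th.leaf_ids
        gadget_index["g1_end_tip"] = th.end_tip
    gadget_index["g1"] = g1.id
    for v in RootedBinaryTree(g1).preorder():
        node_gadget[v.id] = ("root-thorn",)
    g1.parent = None

    backbone = clause_roots + var_roots
    g2_internals = ["g2"] + [f"g2b{t}" for t in range(1, len(backbone) - 1)]
    g2 = _caterpillar(backbone, g2_internals)
    for t in g2_internals[: max(len(backbone) - 1, 0)]:
        node_gadget[t] = ("backbone",)
    if len(backbone) == 1:
        gadget_index["g2"] = g2.id
    else:
        gadget_index["g2"] = "g2"
    gene_root = node("g0", g1, g2)
    node_gadget["g0"] = ("backbone",)
    gadget_index["g0"] = "g0"
    gene_tree = RootedBinaryTree(gene_root)

    # species tree: trunk rho_0..rho_2m, sigma/sigma'_1..n, tau_{1..3,1..n}
    species_thorn_nodes: Dict[Tuple[int, int], FrozenSet[str]] = {}
    cur: Optional[TreeNode] = None
    for j in range(n, 0, -1):
        for h in (3, 2, 1):
            th = build_thorn(n * n, prefix=f"sth{h}_{j}", tip_id=f"t{h}_{j}")
            thorn_root = th.tree.root
            thorn_root.parent = None
            species_thorn_nodes[(h, j)] = frozenset(
                v.id for v in RootedBinaryTree(thorn_root).preorder()
            )
            thorn_root.parent = None
            if cur is None:
                cur = node(f"tau{h}_{j}", thorn_root, node("xtra"))
            else:
                cur = node(f"tau{h}_{j}", thorn_root, cur)
    for j in range(n, 0, -1):
        cur = node(f"sigp{j}", node(f"sp{j}"), cur)
        cur = node(f"sig{j}", node(f"s{j}"), cur)
    for i in range(2 * m, -1, -1):
        cur = node(f"rho{i}", node(f"r{i}"), cur)
    species_tree = RootedBinaryTree(cur)
    trunk = tuple(
        [f"rho{i}" for i in range(2 * m + 1)]
        + [x for j in range(1, n + 1) for x in (f"sig{j}", f"sigp{j}")]
        + [f"tau{h}_{j}" for j in range(1, n + 1) for h in (1, 2, 3)]
    )

    # leaf map
    le: Dict[str, str] = {}
    for i in range(1, m + 1):  # part 1
        le[f"y{i}"] = le[f"yb{i}"] = f"r{2 * i - 1}"
        le[f"yp{i}"] = le[f"ybp{i}"] = f"r{2 * i}"
    for j in range(1, n + 1):  # part 2
        for h in (1, 2, 3):
            le[f"k{h}_{j}"] = f"s{j}"
            le[f"kp{h}_{j}"] = f"sp{j}"
    for leaf in g1_leaves:  # part 3
        le[leaf] = "r0"
    for j in range(1, n + 1):  # parts 4-5
        for h in (1, 2, 3):
            gene_leaves = gene_thorn_leaves[(h, j)]
            for w, gl in enumerate(gene_leaves, 1):
                le[gl] = f"sth{h}_{j}_t{w}"
            le[f"kpp{h}_{j}"] = f"t{h}_{j}"

    recon = ReconInstance(
        gene_tree, species_tree, LeafMap(le), cost_dup=2 * B * n * n, cost_loss=1
    )
    return DLCOPInstance(
        recon=recon,
        budget_b=(10 * B + 2) * n**3 + 121 * n * n,
        B=B,
        alpha=f"epsilon/{20 * B + 4}",
        formula=formula,
        gadget_index=gadget_index,
        node_gadget=node_gadget,
        literal_slots=slots,
        occurrence_slot=occurrence_slot,
        species_thorn_nodes=species_thorn_nodes,
        trunk_nodes=trunk,
        gene_thorn_leaves=gene_thorn_leaves,
    )


def _apx_root_thorn_cut(instance: DLCOPInstance) -> Set[str]:
    """Duplications on the terminal edges of the root (3n-m+1)-thorn: every
    leaf edge except the end tip's, separating all r_0 paralogs."""
    leaves = [
        v
        for v, g in instance.node_gadget.items()
        if g == ("root-thorn",) and instance.recon.gene_tree.node(v).is_leaf
    ]
    if len(leaves) <= 1:
        return set()
    tip = instance.gadget_index["g1_end_tip"]
    return {v for v in leaves if v != tip}


def apx_wellbehaved_solution(
    instance: DLCOPInstance,
    valuation: Valuation,
    chosen: Optional[Mapping[int, int]] = None,
) -> Tuple[SpeciesMap, DuplicationPlacement]:
    """A well-behaved (exactly 5n duplications) solution from any total
    valuation.

    Species map: every internal gene node to the species root rho_0, except
    the root thorn (g1 and descendants), which maps to the leaf r_0; gene
    leaves follow the leaf map.  Placement: per variable one duplication --
    on ``e(nbeta_i)`` when true, ``e(beta_i)`` when false (note the reversed
    convention relative to the decision reduction) -- two per clause on the
    literal edges other than ``chosen[j]`` (default: the lowest satisfying
    position, or position 1 for an unsatisfied clause), and ``3n - m``
    duplications on the root-thorn terminal edges.
    """
    formula = instance.formula
    m, n = formula.m, formula.n
    edges: Set[str] = set()
    for i in range(1, m + 1):
        edges.add(f"betab{i}" if valuation[i] else f"beta{i}")
    for j, clause in enumerate(formula.clauses, 1):
        if chosen is not None and j in chosen:
            c = chosen[j]
        else:
            sat = [h for h, lit in enumerate(clause, 1) if valuation.truth(lit)]
            c = min(sat) if sat else 1
        for h in (1, 2, 3):
            if h != c:
                edges.add(f"lam{h}_{j}")
    edges |= _apx_root_thorn_cut(instance)

    mapping: Dict[str, str] = {}
    G = instance.recon.gene_tree
    for v in G.preorder():
        if v.is_leaf:
            mapping[v.id] = instance.recon.leaf_map[v.id]
        elif instance.node_gadget[v.id] == ("root-thorn",):
            mapping[v.id] = "r0"
        else:
            mapping[v.id] = "rho0"
    return SpeciesMap(mapping), DuplicationPlacement(frozenset(edges))


def apx_solution_from_valuation(
    instance: DLCOPInstance, valuation: Valuation
) -> Tuple[SpeciesMap, DuplicationPlacement]:
    """The proof-constructed solution for a satisfying valuation: exactly
    ``5n`` duplications and total cost below the budget ``b``.  Raises
    :class:`UnsatisfiedClauseError` when the valuation leaves some clause
    unsatisfied."""
    chosen = _chosen_literals(instance.formula, valuation)
    return apx_wellbehaved_solution(instance, valuation, chosen)


def apx_is_well_behaved(
    instance: DLCOPInstance, placement: DuplicationPlacement
) -> bool:
    """True iff the placement uses exactly 5n duplications distributed as
    the structure demands: one per variable gadget on ``e(beta_i)`` or
    ``e(nbeta_i)``, exactly two per clause gadget, and ``3n - m`` in the
    root thorn."""
    formula = instance.formula
    m, n = formula.m, formula.n
    if len(placement.edges) != 5 * n:
        return False
    per_var: Dict[int, List[str]] = {i: [] for i in range(1, m + 1)}
    per_clause: Dict[int, int] = {j: 0 for j in range(1, n + 1)}
    thorn_count = 0
    for e in placement.edges:
        gadget = instance.node_gadget.get(e)
        if gadget is None:
            return False
        if gadget == ("root-thorn",):
            thorn_count += 1
        elif gadget == ("backbone",):
            return False
        elif gadget[0] == "var":
            per_var[gadget[1]].append(e)
        elif gadget[0] == "clause":
            per_clause[gadget[1]] += 1
    for i in range(1, m + 1):
        if per_var[i] not in ([f"beta{i}"], [f"betab{i}"]):
            return False
    if any(count != 2 for count in per_clause.values()):
        return False
    return thorn_count == 3 * n - m


def apx_loss_audit(
    instance: DLCOPInstance, losses_by_edge: Mapping[str, int]
) -> Tuple[Dict[Tuple[int, int], int], int]:
    """Split per-species-edge loss counts into per-thorn and trunk shares.

    The thorn share of clause position (h, j) counts losses on the n^2
    *terminal* edges of its species thorn (where the construction's
    accounting predicts n^2 per duplicated literal edge, 0 for the chosen
    satisfying literal).  Everything else -- the two edges emanating from
    each trunk node, including thorn-root edges, and thorn-internal edges
    -- is the trunk share, bounded by ``121 n^2``.
    """
    S = instance.recon.species_tree
    thorn: Dict[Tuple[int, int], int] = {}
    counted = 0
    for key, nodes in instance.species_thorn_nodes.items():
        total = sum(
            c
            for edge, c in losses_by_edge.items()
            if edge in nodes and S.node(edge).is_leaf
        )
        thorn[key] = total
        counted += total
    trunk = sum(losses_by_edge.values()) - counted
    return thorn, trunk


def apx_valuation_from_solution(
    instance: DLCOPInstance, placement: DuplicationPlacement
) -> Valuation:
    """Interpret a well-behaved solution: a duplication on ``e(beta_i)``
    sets x_i false, on ``e(nbeta_i)`` true."""
    if not apx_is_well_behaved(instance, placement):
        raise ConstraintError("placement is not well-behaved")
    assignment = {
        i: f"betab{i}" in placement.edges
        for i in range(1, instance.formula.m + 1)
    }
    return Valuation(assignment)
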