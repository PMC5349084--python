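# Methods

## Model

A reconciliation of a gene tree *G* with a species tree *S* under a leaf
map *Le* is represented as a labeled coalescent tree (LCT): a species map
*M*, a locus set, and a locus map, subject to five constraints (leaf
extension, ancestor consistency, distinct loci for paralogous leaves, no
unused loci, unique locus creation).  `validate_lct` checks all five and
returns violation records carrying the constraint number and witnesses, so
callers can assert on *which* constraint failed.

The workflow order is fixed and enforced by `score_placement`: the species
map is chosen on the input gene tree; implied speciation nodes are then
inserted; the locus map is defined on the augmented tree.  Duplications
are counted as locus changes along gene edges and depend only on the locus
map; losses are counted per species branch as loci present at the top of
the branch (`tops(s) = bottoms(p(s))`) or arising within it but absent
from its bottom, with distinct loci counted independently on the same
branch.  `tops` of the species root is empty (the root has no parent
branch, and losses are only defined on non-root branches).  Coalescence
events carry zero cost everywhere in this package and are not counted.

### Implied speciation

A node *g* with parent *p* triggers an insertion when its edge strictly
descends in the species tree and either the edge skips a species branch
(`p(M(g)) != M(p)`) or *p* keeps a child in its own species (*p* is not a
speciation node).  The inserted node subdivides *e(g)* and maps to
`p(M(g))`.  We apply the rule to **all** non-root nodes, leaves included:
loss counting requires loci to be tracked through every species branch a
terminal gene edge spans, and with leaves excluded a gene leaf deep in the
species tree would silently skip branches.  The fixpoint is canonical: it
equals the direct per-edge construction that subdivides each gene edge
once per species node strictly between the endpoint images, plus once at
the upper image when the parent is not a speciation node.  The procedure
is therefore idempotent and order-invariant; `add_implied_speciations`
takes an optional `order_rng` that randomizes processing order purely so
tests can assert that invariance.  Inserted ids are
`<original child>@<species>`, making augmented trees byte-reproducible.

### Placement equivalence

Locus maps and duplication placements (edge sets separating every
paralogous leaf pair) are interchangeable: `placement_from_locus_map`
collects the locus-changing edges; `locus_map_from_placement` numbers the
connected components left after removing the placement, by preorder
discovery (the root's component is 0).  Locus identity is meaningful only
up to bijection; all comparisons are partition-based.  Duplications are
permitted on edges entering implied speciation nodes (nothing in the
constraints forbids it, and the locus map ranges over the full augmented
tree).

## Solvers

* `min_dup_exact` — minimum multicut on the gene tree (terminal pairs =
  paralogous leaf pairs) by branch and bound: pick the uncovered pair with
  the shortest path, branch on its edges in lexicographic order.  The
  admissible lower bound is the larger of a greedy edge-disjoint
  uncovered-path packing and, when that fails to prune and at least 8
  pairs remain open, the fractional-multicut LP relaxation (scipy/HiGHS)
  rounded up.  The guard defaults to 40 gene-tree edges and is an error,
  not a truncation.
* `min_dup_approx` — the classical primal-dual factor-2 multicut scheme
  for trees: process internal nodes bottom-up, raise each still-connected
  pair's dual at its lca until an edge goes tight, then reverse-delete.
  Slacks are exact rationals (`fractions.Fraction`), so tie behavior is
  deterministic.  The factor is asserted against the exact solver in
  tests; a polynomial-time approximation scheme for tree multicut exists
  but is deliberately out of scope — factor 2 suffices to exercise the
  constructions.
* `enumerate_species_maps` — every constraint-1/2 species map exactly
  once: each internal node's image ranges over the species path between
  the lca of its descendant leaf images and its parent's image.
* `solve_dlcop` / `solve_dlcdp` — with loss cost 0 the optimum provably
  collapses to duplication cost x minimum multicut (any valid species map
  will do), so the exact multicut solver is used directly.  Otherwise the
  solver enumerates species maps, augments per map, and enumerates
  placements over the augmented edges up to `#pairs + slack` edges
  (slack defaults to 1; no optimum needs more duplications than pairs when
  losses cost >= 0, and the cap is recorded in the result for audit).
  The decision solver short-circuits at the first candidate within budget.
  A switch (`exclude_terminal`, default off, rejected when losses are
  priced) restricts the search to non-terminal edges; with free losses any
  terminal-edge duplication can be pushed up one level, so the optimum is
  unchanged while variable-gadget branching halves.

Tie-breaking everywhere is lexicographic on node ids, so arg-min results
are reproducible across runs and platforms.  Costs parsed from the CLI
stay integers whenever written as integers; all constructed instances use
integral costs, so no floating-point comparisons arise there.

## Formula compilers

`parse_dimacs` normalizes before anything else: in-clause duplicate
literals are deduplicated (under 3 distinct literals left is an error),
tautological clauses are dropped with a warning, and unused variables are
compacted — so *m <= 3n* holds for every compiled formula, which the
budget arithmetic of the optimization construction uses.

The decision compiler (`build_np_instance`) realizes every "arbitrary
binary tree" in the construction as a left caterpillar with deterministic
labels.  For a single clause the variable-gadget chain degenerates to a
cherry (the gadget has four leaves).  The decision parameter is *2n + m*
with duplication cost 1 and loss cost 0.  `np_solution_from_valuation`
places one duplication per variable gadget (true branch when true) and two
per clause on the literal edges not chosen as satisfying (lowest-index
satisfying literal, a deterministic refinement of "any one"); the inverse
extraction reads the variable from which alpha-path carries a duplication
and rejects gadgets with both or neither side cut.

The optimization compiler (`build_apx_instance`) uses thorn gadgets
(caterpillars with a designated deepest end tip): an (n²−1)-thorn per
literal occurrence in the gene tree paired index-by-index with an
n²-thorn per clause position in the species tree — the species thorn has
one extra leaf, its end tip, which receives the clause gadget's k″ leaf;
this is the natural reading of "the leaf with the same index" given the
off-by-one sizes.  Costs are duplication 2Bn², loss 1, with *B* the
attained maximum occurrence count unless pinned by the caller.  The
construction needs at least two clauses (thorn sizes degenerate at n = 1);
a variable polarity with zero occurrences collapses its thorn chain so the
β′ node becomes the bare y′ leaf; when *m = 3n* the gene tree's root thorn
has a single leaf.  Note the true/false edge conventions of the two
compilers are opposite (decision side: duplication on e(β_i) means true;
optimization side: duplication on e(β̄_i) means true); each follows its own
correctness argument, and the pair is easy to conflate.

`apx_loss_audit` splits per-branch losses into per-thorn shares (losses on
each species thorn's n² terminal edges, where the accounting predicts n²
per duplicated literal edge and 0 for the chosen satisfying literal) and a
trunk share (everything else, including thorn-root edges, which emanate
from trunk nodes and belong to the trunk bound of 121n²).

## Generators

`random_tree` draws shapes by recursive uniform splits; `random_instance`
draws a leaf map where each gene leaf joins an existing species group with
the given paralogy probability, else takes a fresh species leaf;
`random_cnf` draws normalized formulas where every variable occurs at
least once (hence *m <= 3n* is required) and at most *B* times, retrying
deterministically when a draw corners itself.  All generators are pure
functions of their arguments with one explicitly seeded PRNG per call.

The generators emulate only the combinatorial shape of reconciliation
inputs — label structure, paralogy collisions, occurrence bounds.  They do
not emulate birth-death gene evolution, coalescent locus histories, or any
correlation between gene and species topology; passing tests establish the
correctness of the combinatorial machinery on such inputs, not inference
quality on biological data.

## Problem sizes and numerical choices

The test suite runs at desk scale, chosen to finish in seconds to minutes:
exhaustive reduction soundness over every normalized two-clause formula on
three variables plus 200 random formulas up to m = 5, n = 4; 500 random
instances for the placement equivalence; 200 instances of at most 12
gene-tree edges for the approximation factor (exact side cross-checked
against an exhaustive subset oracle); loss-accounting audits at n = 2 and
n = 3; and the unsatisfiable 8-clause formula over 3 variables for the
decision no-side, solved with the terminal-edge restriction.  The LP lower
bound uses a 1e-9 slack before rounding up to guard against solver
round-off; everything else is exact integer or rational arithmetic.

## Limitations

* The exact solvers are enumerative by design; guards (40 edges for
  multicut, 12 for the full loss-aware enumeration) keep them honest, and
  larger instances need the approximation or a different algorithm (the
  known dynamic program for DLC reconciliation is out of scope).
* The full optimization solver caps placements at `#pairs + slack` edges;
  no bound on the duplications an optimum may use under positive loss
  costs is known to us, so the cap is reported rather than hidden.
* The gap constant of the approximation-hardness construction is kept
  symbolic (`epsilon/(20B+4)`); the package verifies the construction's
  structural and accounting identities on concrete instances and makes no
  asymptotic claim.
* Non-binary input trees, branch lengths, and probabilistic reconciliation
  are out of scope.
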