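# dlcrecon

Maximum-parsimony reconciliation in the duplication-loss-coalescence (DLC)
model, for people studying the computational structure of gene-tree /
species-tree reconciliation: scoring reconciliations, solving small
instances exactly, and compiling Boolean formulas into reconciliation
instances that make the problem's hardness tangible on a desk.

## The model

Given a rooted binary gene tree *G*, species tree *S*, and a leaf map
*Le: L(G) → L(S)* (gene leaves mapped to the species that carry them — not
necessarily one-to-one: leaves sharing an image are paralogs), a
reconciliation is a *labeled coalescent tree* (LCT): a species map
*M: V(G) → V(S)* extending *Le* ancestor-consistently, plus a locus set and
a locus map assigning every gene node a locus, such that paralogous leaves
carry distinct loci and every locus is created exactly once.  Implied
speciation nodes are inserted so every gene branch crosses species branches
one at a time.

Events are priced per branch: a **duplication** wherever the locus changes
along a gene edge (cost *C_d*), a **loss** on a species branch for every
locus present at its top (or created within it) but absent at its bottom
(cost *C_ℓ*); coalescence is free.  The optimization problem asks for an
LCT minimizing *d·C_d + ℓ·C_ℓ*.

Two structural facts drive the implementation:

* **Placement equivalence** — locus maps correspond exactly to
  *duplication placements*: edge sets of *G* separating every paralogous
  leaf pair, with |D| = number of duplications.  Minimizing duplications
  alone is therefore minimum multicut on a tree with the paralog pairs as
  terminals.
* **Hardness gadgets** — 3-CNF formulas compile into reconciliation
  instances: variable gadgets force one duplication on a true or false
  branch, clause gadgets force two of three literal branches, so a
  reconciliation with at most *2n + m* duplications exists exactly when
  the formula is satisfiable.  A second compiler (thorn gadgets, loss cost
  1, duplication cost *2Bn²*) makes per-clause loss counts — *2n²* when
  satisfied, *3n²* when not — separate satisfiable from barely-satisfiable
  MAX3SAT(B) formulas, the constructive core of the model's
  approximation-hardness.

The package provides the scoring machinery (`dlcrecon.model`), exact
branch-and-bound and primal-dual 2-approximate multicut solvers plus full
optimization/decision solvers (`dlcrecon.solvers`), both formula compilers
with executable valuation↔solution maps (`dlcrecon.reductions`),
deterministic generators (`dlcrecon.generate`), and a `dlc` command line.

## Worked example

Compile the one-clause formula (x₁ ∨ ¬x₂ ∨ x₃) and solve it:

```
$ printf 'p cnf 3 1\n1 -2 3 0\n' > f.cnf
$ dlc reduce --mode np --cnf f.cnf --out bundle
m       3
n       1
gene_leaves     18
species_leaves  10
decision_k      5
$ dlc mindup --exact --gene bundle/gene.nwk --species bundle/species.nwk \
      --leafmap bundle/leafmap.tsv
duplications    5
optimal True
placement       beta1 beta2 beta3 deltap1 k1_1
```

The instance needs at least one duplication per variable gadget (the
paralogous leaf pairs y_i/ȳ_i) and two in the clause gadget (the three
k-leaves on one species), so 5 is optimal; `dlc solve --decision 5` exits
0 (yes) and `--decision 4` exits 1 (no).  The placement decodes to a
valuation: a duplication on `beta1` (the true branch of x₁) sets x₁ true,
which satisfies the clause:

```
$ dlc verify --bundle bundle --placement placement.tsv
placement_size  5
valid   True
within_budget   True
valuation       1=T 2=T 3=T
satisfies_formula       True
```

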