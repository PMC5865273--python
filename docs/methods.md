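# Methods

## Model

A reference taxonomy is a rooted tree `T` whose leaves are reference
sequences; internal nodes are higher ranks.  A read `i` arrives with a
non-empty candidate set `M_i` of leaves (the sequences it mapped to equally
well).  Let `T_i` be the subtree rooted at the LCA of `M_i`.  Annotating the
read at a node `j` of `T_i` predicts the leaves of clade(`j`) positive, so

    TP = |M_i ∩ clade(j)|,  FP = |clade(j) \ M_i|,
    FN = |M_i \ clade(j)|,  TN = leaves(T_i) − TP − FP − FN.

The working assumption is that reads come from sequences that are in the
reference (novel-taxon reads are out of scope; they belong to clustering
methods, not taxonomic annotation).

Six error indicators score a quadruple: Yule φ (= Matthews correlation),
Youden `J`, two-point AUC, `F`-measure, Jaccard `C`, Rand `R`.  Whenever a
denominator of the chosen formula is zero the score is defined as 0; for φ
the rule is applied to the whole radicand (any zero factor ⇒ score 0), and
for AUC to the pair of denominators (TP+FN and FP+TN).  `J = 2·AUC − 1` and
`C = F/(2−F)` are strictly monotone couplings, so those pairs always share
argmax sets.

**Maximisation is exact.**  Every indicator is compared through an integer
pair `(num, den)` whose ratio orders identically to the score: the five
rational indicators use their exact value; φ = a/√d is ordered through its
signed square `a·|a|/d` (a strictly increasing transform).  Cross
multiplication in integers decides every comparison, so ties are ties of
the real numbers, never float artefacts.

**Only relevant nodes are scored.**  A node of `T_i` is *relevant* if it is
a candidate or the LCA of two or more candidates (the LCA skeleton).
Replacing any node `j` by the LCA of the candidates inside clade(`j`) keeps
TP and FN fixed while removing false positives, which cannot decrease any
of the six indicators — so the per-read maximum over all of `T_i` is
attained on the skeleton, and only its ≤ 2|M_i|−1 nodes are evaluated.  The
skeleton is computed from consecutive leaves in depth-first order (|M|−1
LCA calls); a property test checks it against the all-pairs definition.

The full argmax set is carried forward; ties are *not* broken per read.

## Set-cover disambiguation

Elements are read ids; each candidate node names the subset of reads for
which it is optimal.  For a cover `C'`, overlap = Σ|chosen| − |X| counts
residual ambiguity, and a least-total-size cover is always a least-overlap
cover (total size differs from overlap by the constant |X|).  A
least-cardinality cover is not: in the family
{1,2},{3,4},…,{n−1,n},{1..n−1},{2..n} the two chains cover with size 2 and
overlap n−2, while the matching has overlap 0.

Solvers:

* **greedy** — repeatedly take the subset covering most uncovered elements;
  ties by lexicographic subset name (a reverse-lexicographic mode exists
  because tie policy changes which of the equally sized solutions appears).
* **exact** (`min_cardinality_cover`, `min_total_size_cover`) — implicit
  enumeration: branch on the uncovered element with the fewest covering
  subsets, in name order, pruning branches whose cost exceeds the
  incumbent.  Elements with identical membership signatures are collapsed
  to weighted elements first (weights count in every total), which keeps
  the search size bounded by the number of distinct signatures rather than
  the number of reads.  Among optimal covers the lexicographically smallest
  sorted name tuple is returned, making outputs reproducible.  The exact
  solvers refuse families larger than 40 subsets; real instances are tiny
  because most reads are unambiguous after argmax filtering.

Reads claimed by several chosen nodes split their unit weight uniformly
(ancestry-aware splitting is deliberately not attempted); abundances are
exact `Fraction`s summing to 100%, printed at 2 decimals alongside a
full-precision column.  `rollup_profile` aggregates at a named rank, with
an `Other` bucket for nodes lacking a ranked ancestor.

## Enumeration benchmarks

Two exhaustive studies over synthetic topologies:

* **Confusion distribution** — over every non-empty leaf subset and every
  internal node of the whole tree, tally (TP,FP,TN,FN) with whole-tree
  negatives.  Its TP+FN marginal is `C(n,k)·(#internal nodes)` regardless
  of topology, which is the formal sense in which balanced and imbalanced
  taxonomies pose equally balanced classification problems.
* **Correct-annotation totals** — for every subset `M`, find the internal
  nodes maximising an indicator and add, for each maximising node, the
  number of source leaves of `M` inside its clade (its TP); ties contribute
  once per tied node.  Candidate nodes default to the internal nodes at or
  under the LCA of `M` (`candidates="lca"`, singletons annotated at their
  leaf, which is always correct); `candidates="global"` scores every
  internal node instead.  The two coincide on perfect trees.  Leaves are
  never candidates in either mode.

Both are vectorised with numpy int64 arithmetic (subset-membership matrix
times clade matrix, then cross-multiplied running argmax), processing 2¹⁶
subsets per block; the 16-leaf run is ~10⁶ evaluations per indicator and
takes well under a minute.  A pure-python `Fraction` brute force in the
test suite independently reproduces the counts on trees of ≤ 7 leaves.

### Topology builds

`complete_binary_tree(n)` defaults to the maximally balanced recursive
⌈n/2⌉/⌊n/2⌋ split, which minimises the total cophenetic index (sum over
leaf pairs of their LCA's depth) among binary trees; `caterpillar(n)`
maximises it.  For non-power-of-two `n` a second build is provided,
`split="left_packed"` (largest power of two on the left — equivalently the
perfect tree on the next power of two restricted to its first `n` leaves),
and the benchmark's complete-tree series uses it: calibration of the
enumeration at small `n` selects this build and the under-LCA candidate
convention as the pair that reproduces the published totals, and all four
published totals are reproduced for twelve of the fifteen tree sizes
(n = 2–5, 7–9, 11, 13–16).  The published entries at n = 6, 10 and 12 are
not reproducible under any single convention we could construct —
exhaustive search over every 6-leaf topology (including polytomies) and a
wide grid of counting conventions shows those entries mutually contradict
the n = 11 and n = 14 entries, and the n = 6 entry also inverts the
otherwise universal φ < F ordering — so they are treated as erroneous and
left failing in the acceptance suite rather than fitted.

## Synthetic data

Tests generate all inputs programmatically: topology generators above plus
`random_binary_tree(n)` (random recursive splits — shapes vary but are not
uniformly distributed), random candidate sets of 1–4 leaves per read, and
random set-cover families.  These exercise every code path with exact
oracles, but they idealise real samples in known ways: candidate sets are
uniform rather than clustered by sequence similarity, reference trees are
tiny and binary, and E-value structure is synthetic.  Passing tests
therefore certify algorithmic correctness (argmax exactness, cover
optimality, conservation laws), not end-to-end accuracy on real
communities, which depends on the mapper and reference quality.

## Numerical and degenerate-input choices

* All scores exact (integer/Fraction); no tolerance is needed anywhere in
  the library.  TSV output prints floats at 12 significant digits plus
  exact fractions where a profile is involved.
* E-values compared as `Decimal` after parsing, so `1e-30`, `1E-30` and
  `1.0e-30` tie exactly; per read, exactly the records at the minimum
  E-value survive.
* Empty candidate sets, unknown labels, duplicate read ids, orphan taxids,
  multiple dump roots, out-of-order lineage ranks and oversize exact-solver
  instances all raise typed errors naming the offender; unresolvable
  subjects in lenient mode are reported as unassigned, never dropped.
* Enumeration bounds: 20 leaves for distributions, 16 for correctness
  totals (int64 headroom and runtime both comfortable).

## Limitations

* No ancestry-aware read splitting in the abundance step.
* No weighted/partial cover variants; no LP rounding.
* The exact solvers are for post-argmax instances (≤ 40 subsets), not for
  general set-cover workloads.
* Caterpillar correct-annotation series are self-consistency-checked only;
  no published reference values exist for them.
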