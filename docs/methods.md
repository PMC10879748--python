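# Methods

## Model

A level-1 semi-directed network with one four-node hybridization cycle
`h – v1 – v3 – v2 – h` partitions the taxa into four clades: the hybrid
clade `n0` below `h`, the parent-side clades `n1` (via edge `h–v1`) and
`n2` (via `h–v2`), and `n3` opposite the hybrid node at `v3`.  Gene trees
evolve within the network under the multispecies coalescent: within every
edge, lineages coalesce pairwise at rate 1 per pair (time in coalescent
units), and a lineage entering `h` follows `h–v1` with inheritance
probability `γ`, independently per lineage and per gene.  The root may be
placed anywhere not below the hybrid node without changing unrooted quartet
frequencies; simulation roots at `v3`.

The model parameters are the eight internal branch lengths — clade stems
`t0..t3` (junction of a sampled pair to its cycle node), hybrid edges
`t01`, `t02`, cycle edges `t13`, `t23` — through `z_e = exp(-t_e) ∈ (0,1]`,
plus `γ ∈ [0,1]`.  Pendant edges never appear in any CF formula; only
branches on which two sampled lineages can travel together matter.

## CF polynomials by scenario enumeration

A quartet class `(i,j,k,l)` records how many of four sampled taxa come from
each clade; informative classes have entries ≤ 2 (three or more taxa from
one clade see the cycle only through pendant edges) and entry ≤ clade size.
The reference signature (2,2,2,2) has 19 classes; signature (1,1,1,2) has
4, giving 12 CF equations.

Each class's CF triple is derived exactly by enumerating hybrid scenarios:

1. If both hybrid-clade lineages are drawn, they coalesce on the clade-0
   stem with probability `1 − z0` — which fixes the quartet split — or
   survive with probability `z0`.
2. Each surviving clade-0 lineage independently chooses `h–v1` (probability
   `γ`) or `h–v2`; if an uncoalesced pair chooses the same hybrid edge, its
   junction is kept at `h` so the hybrid edge stays internal to the quartet.
3. Conditional on a scenario the network resolves to a species tree with
   known attachment points on the path `v1 – v3 – v2`.  For a 4-leaf
   species tree whose internal (2|2-separating) path has total length `T`,
   the gene-quartet probabilities are `1 − (2/3)e^{-T}` for the tree's own
   split and `(1/3)e^{-T}` for the other two — computed here by locating
   the separating edges in the scenario tree, so degenerate placements
   (multiple lineages at one node, star trees) fall out correctly.
4. The class CF is the probability-weighted sum over scenarios, expanded as
   a polynomial over ℚ in the `z` variables and `γ`.

CF slots follow a fixed convention: slot 1 is the split grouping same-clade
pairs (for the class (1,1,1,1): pairing the `n0` taxon with the `n1`
taxon); the remaining two slots are ordered by sorted taxon labels when
instantiated on data.  For every class containing a same-clade pair the two
minor CFs are symbolically equal, by exchangeability of same-clade
lineages; the class (1,1,1,1) has three generically distinct CFs.

Correctness is cross-checked two independent ways in the test suite: a
Monte-Carlo coalescent simulator on the rooted network (agreement within
three binomial standard errors), and the displayed-tree limit — at `γ = 0`
or `1` the engine must reproduce quartet CFs computed on the displayed tree
by an independent four-point-condition oracle.

## Invariants

For a signature the CF system is a polynomial map `a = f(z, γ)`.  Any
polynomial in the `a` variables vanishing identically under this
substitution is a phylogenetic invariant; it holds for every parameter
value, which is what allows scoring candidates without estimating branch
lengths or `γ`.

*Trivial* invariants are structural: per class the sum-to-one relation and,
for classes with a same-clade pair, minor equality (signature (1,1,1,2):
4 + 3 = 7 of them).  *Nontrivial* invariants are derived in reduced
coordinates that absorb the trivial relations — per pair-class the shared
minor `m = (a2+a3)/2`, plus `u1 = a1`, `u2 = a2` of the class (1,1,1,1) —
by numeric interpolation: sample model CF vectors at ≥ 5× as many random
parameter draws as monomials (branch lengths Uniform(0.05, 3), `γ`
Uniform(0.05, 0.95), fixed internal seed so derivation is reproducible),
take the SVD null space of the monomial evaluation matrix up to the maximum
degree, bring it to reduced row echelon form, rationalize coefficients
(denominators ≤ 1000), and **verify each candidate symbolically** by
substituting `f` and expanding to the zero polynomial.  Unverifiable
candidates are dropped; in practice every null vector verifies.  A
symbolic-elimination route (Gröbner basis of the graph ideal, eliminating
the parameters) is available and agrees on small signatures; interpolation
is the default because elimination over 20+ variables is impractical in a
general-purpose symbolic engine.

Shipped invariant sets use maximum degree 2.  Degree 3 was derived and
evaluated for the signatures where degree 2 leaves residual degeneracies
(see below): it adds no discriminating polynomial — the degeneracies are
exact variety containments — while substantially increasing evaluation and
verification cost, so degree 2 is the package default;
`derive_invariants(..., max_degree=3)` remains available.

Two structural facts discovered during derivation and enforced in the code:

* **Signature (2,1,1,1) has no nontrivial invariants.**  Its reduced CF map
  has 5 coordinates but 6 effective parameters with generic Jacobian rank
  5: the image is dense, the elimination ideal is exactly the trivial
  relations.  The deriver detects dominance via the Jacobian and returns
  the trivial-only set.
* **Swapping clades `n1` and `n2` is a model symmetry.**  Invariant sets of
  swapped signatures are images of each other under the induced permutation
  of CF coordinates, and for self-symmetric signatures the derived set is
  closed under that permutation.  Consequently a candidate partition and
  its clade-swapped partner always receive identical invariant scores (to
  float summation order, < 1e-12).

Sets are cached as JSON (one file per signature: rational coefficients as
integer pairs, monomials as index tuples, provenance, SHA-256 checksum);
loading verifies the checksum and re-validates vanishing on 10 random
parameter draws.

### The published five-taxon basis

The ten-polynomial Gröbner basis published for the five-taxon network
(1,1,1,2) uses an a-variable numbering whose global order is not
reconstructable; the package matches its four index triples to canonical
(class, slot) indices by exhaustive search over class assignments and slot
orders, accepting the assignment under which all ten polynomials vanish on
model CFs.  The match is unique only up to the `n1↔n2` swap (the signature
is self-symmetric); the representative with identity slot order is used.
The resolved mapping sends triple (a28, a29, a30) to the class (1,1,1,1)
and the leading index of each remaining triple to a major slot, matching
the visible sum-to-one/minor-equality structure of the printed list.

## Scoring, ranking, ties

The invariant score of a candidate is the L2 norm of all its invariants
(trivial + nontrivial) at the observed a-vector.  Observed CFs map to the
a-vector by enumerating all realizations of each class on the candidate's
clades and averaging each slot across realizations (an unbiased estimator
of the shared true CF; the class (1,1,1,1) on signature (2,2,2,2) has 2⁴ =
16 realizations).  Raw norms are compared across signatures exactly as the
ranking procedure prescribes; an optional normalized score (L2 /
√#invariants) is provided but not default.

Ranking is deterministic: stable sort with canonical partition text as
tiebreak, so symmetric pairs appear adjacently.  **Rank counting treats
scores within 1e-12 as tied** (counted favorably).  This matters because of
a model degeneracy: for true networks with a singleton parent clade
(`n1 = 1` or `n2 = 1`), certain rotated candidates — e.g. truth
`n0=A | n1=B | n2=CD | n3=EF` versus candidate `n0=A | n1=CD | n2=EF |
n3=B` — have invariant scores that are *exactly* zero on the true CFs.
This was verified in exact symbolic arithmetic and persists for all
parameter values; a constrained parameter fit cannot reproduce the point
(the true CF point lies on the competitor's Zariski closure but not its
image), so no polynomial invariant of any degree separates these
candidates, and the observed ~1e-16 score differences are pure
floating-point noise.  With tie-tolerant counting the true partition (or
its symmetric partner) is rank 1 on exact CFs for every supported
signature; hybrid-clade placement remains uniquely resolved for the
signatures with two taxa in both parent clades.

For more than eight taxa, every candidate of every eight-taxon subset is
pooled into one global ranking.  The best candidate is the backbone; each
missing taxon is assigned the clade it occupies in the highest-ranked
candidate that contains it *and* agrees with the backbone on the clade of
every shared taxon.  This compatibility rule is one concrete reading of
"placement in the next-best network"; each placement is logged with the
rank it came from so users can audit it, and a taxon with no compatible
candidate is reported unplaced rather than guessed.

## Synthetic data

The generator produces the simulation study's four input types at its
stated conditions (defaults: every internal branch 1.0 coalescent unit,
`γ = 0.3`, 30 replicates):

* **Exact CF tables** — one row per four-taxon subset, from the CF
  polynomials; on networks with three-taxon clades (used by the 9/10-taxon
  proof of concept) the within-clade topology is a caterpillar over sorted
  labels with a 1.0 internal branch, pair draws adjust the effective stem,
  and three-from-one-clade quartets get tree CFs from the caterpillar
  branch.
* **Gaussian perturbation** — i.i.d. zero-mean noise with σ ∈ {5e-4, 5e-5,
  5e-6}, clipped to [0,1], not renormalized by default (σ is tiny; a
  renormalize flag exists).
* **Multinomial quartet sampling** — per quartet, gene-tree counts in
  {100, 1000, 10000} drawn from the exact CF triple.  Quartets are sampled
  independently: this matches the per-quartet marginal of gene-tree
  sampling but not the correlation of quartets within a gene.
* **Full coalescent gene trees** — event-driven simulation on the rooted
  network (independent hybrid choices per lineage per gene), emitted as
  topology-only Newick; quartet frequencies counted from the output agree
  with the CF polynomials within Monte-Carlo error and do preserve
  within-gene correlation.

What the generator does *not* emulate: sequence evolution and gene-tree
estimation error (the study's seq-gen/IQ-Tree stage).  Tests passing on
synthetic data therefore demonstrate correctness of the CF-level method and
its noise robustness, not robustness to systematically biased gene-tree
estimates; the Gaussian setting is the stand-in for estimation error.

## Numerical choices

* Vanishing tolerance on model-generated data: 1e-8 (acceptance), 1e-10
  (soundness tests); derivation SVD rank threshold 1e-9 relative;
  rationalization denominators ≤ 1000, residual ≤ 1e-6.
* Rank ties: scores within 1e-12 are equal (see above).
* Derivation seed is a fixed package constant (reproducible caches);
  all simulation randomness flows from user-supplied seeds through
  `numpy.random.default_rng`.
* Problem sizes in the shipped checks: 100 parameter draws for
  printed-basis vanishing, 1000 draws for soundness, 30 replicates per
  noise/sampling setting, 10⁵ Monte-Carlo draws for the CF closed-form
  check, 10⁴ gene trees per quartet in the recovery-rate check.
* The star-tree limit (all `t = 0`) and `γ ∈ {0, 1}` displayed-tree limits
  are exact degenerate cases of the engine and are tested as such.

## Limitations

* Only four-node cycles on level-1 networks; topology within clades is
  neither used nor inferred, and `n1` versus `n2` cannot be oriented
  (symmetric networks tie exactly).
* Candidate clades are restricted to sizes 1–2 (larger clades are reached
  through the >8-taxon subset procedure); invariant sets exist for the 15
  signatures with 5–8 taxa.
* Branch lengths and `γ` are not estimated; the score has no goodness-of-fit
  threshold — it ranks candidates, it does not test them.
* Five-taxon data cannot uniquely place the cycle even with exact CFs
  (the (2,1,1,1) candidate family is score-zero on any five-taxon truth);
  with singleton parent clades the rotated-candidate ties described above
  mean the method should be read as reducing the candidate set, exactly as
  intended for its top-m use.
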