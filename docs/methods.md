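# Methods

`motifevo` operationalizes a classic comparative study design for protein
families such as the selenium-binding proteins (SBP/SELENBP1): short
functional motifs — the CC selenium-binding pair, the thioredoxin-like
CxxC/CSSC redox motif, the *DEL endoplasmic-reticulum retention signal,
the HxD and HxxHC metal-coordination motifs, the clathrin-binding box
pLφpφp — are located in every family member, their lineage-specific
variant forms are classified, and their gains, losses and modifications
are mapped onto a phylogeny. This note records the models, parameter
choices and numerical conventions behind each stage.

## Motif grammar and variant classification

A motif is a sequence of position specifications: a literal residue, the
wildcard `x` (any of the 20 canonical residues), an enumerated class such
as `[GKRDN]`, or a named property class. The two property classes are

* φ (bulky hydrophobic) = {F, I, L, M, V, W, Y}
* p (polar) = {C, D, E, H, K, N, Q, R, S, T, Y}

These memberships are this package's concretization of the verbal
definition of the clathrin box ("p = polar, φ = bulky hydrophobic");
tyrosine is deliberately in both classes. Both are overridable in the
catalog config. The unknown residue `X` satisfies **no** position,
including `x`: an undetermined residue must never fabricate a motif hit.

Scanning reports every satisfying window, including overlapping and
nested occurrences (CC and CxxC are independent reports even when they
share residues). Coordinates are 1-based inclusive.

Variant classification aligns an observed window against the pattern
under unit costs: a residue violating its position spec costs one
substitution, insertions and deletions cost one each, and a satisfying
residue costs nothing. The minimum-edit alignment is computed by dynamic
programming with a deterministic traceback that prefers
match/substitution over insertion over deletion, which also places edits
leftmost among ties. The status summarizes the edit composition
(`canonical` at distance 0; distances above the budget, default 2, give
`absent`). The spec'd status enum has no "mixed" entry; windows whose
optimal path mixes edit types take the majority type, ties broken
substitution > insertion > deletion. The default edit budget of 2 covers
every named lineage variant of the canonical catalog (CSSS, CCSS, CSSSC,
*DEI, *SEV, HxE, HxN, RxD are all within 2 edits).

## Alignment conservation statistics

Per-column entropy and information content follow the sequence-logo
convention: with residue frequencies f_a over the non-gap residues of a
column (gaps excluded from the denominator, WebLogo's default),

    H = −Σ f_a log2 f_a,   R = max(0, log2 20 − H − e_n),
    e_n = 19 / (2 ln 2 · n)

where e_n is the Schneider–Stephens small-sample correction for a
20-letter alphabet and n the non-gap count. Negative corrected values
are clipped to zero. A fully conserved column over 129 sequences scores
log2 20 − e_129 ≈ 4.322 − 0.106 ≈ 4.216 bits.

An *invariant* column requires every row to carry the same residue with
no gaps anywhere — the stricter of the two readings of "100% identical",
adopted because structure-restricted censuses (columns resolvable in a
crystallographic model) imply fully occupied columns. Both the
unrestricted census and a user-supplied column-subset census are
provided so either reading can be evaluated on real alignments
(`scripts/external_validation.py`).

The motif-occupancy matrix locates each motif's *anchor windows*:
canonical hits are found on the degapped rows, projected to alignment
columns, and maximal column runs supported by at least 25% of rows
become anchors. Every row is then called at each anchor — `canonical` if
one of its hits overlaps the anchor, otherwise `variant:<text>` when its
residues across the anchor columns classify within the edit budget,
otherwise `absent`. The 25% support threshold is this package's
parameter (the original analyses located motifs by eye); it is exposed
as an argument. With few rows, chance canonical hits elsewhere in the
sequence can clear the threshold and create spurious anchors, so
downstream analyses should select anchors by their column interval, as
the end-to-end tests do.

## Homology profiling

Presence of a query protein in a proteome is decided by the rule used in
SBP homologue screens: best-scoring target with **identity ≥ 70%** and
**query coverage > 80%**. Instead of a heuristic database search the
package uses an exact Smith–Waterman–Gotoh local aligner (affine gaps)
with BLAST's protein defaults: BLOSUM62, gap open 11, extend 1 (a gap of
length k costs 11 + k). The dynamic-programming fill is JIT-compiled
with numba; the first call in a process compiles for a few seconds.

Conventions, where the verbal rule is ambiguous:

* identity denominator = all alignment columns, gap columns included
  (BLAST's convention);
* coverage = aligned query span / query length (NCBI's "query cover"),
  not the count of aligned residues;
* identity threshold non-strict (≥ 70), coverage strict (> 80);
* one best-scoring target per proteome is thresholded (single-best-hit);
* tie-breaking is deterministic: the highest-scoring end cell with the
  smallest coordinates, traceback preferring substitutions over gaps
  (favoring shorter, leftmost alignments). The optimal *score* is
  tie-independent and is what the oracle tests check.

Exact alignment makes results self-contained and deterministic; identity
values on real data may differ slightly from BLAST's heuristic HSPs.

## Parsimony mapping of motif events

Per-leaf motif states (canonical, each variant string, absent — or a
coarse present/absent mode) are unordered characters. Minimum change
counts use Fitch's small parsimony, generalized to multifurcations by
Hartigan's set-counting rule: at each internal node the states contained
in the largest number of child sets are kept and each child set missing
all of them contributes one change. The tree is used as rooted exactly
as parsed; no re-rooting (analyses of this family conventionally root
with the bacterial methanethiol-oxidase outgroup).

One optimal ancestral labeling is produced deterministically: a node
reuses its parent's state when its state set allows it, otherwise takes
the first-child-preferred member of its set. The change *count* is
tie-independent; the reported change *branches* are one optimal
placement. A consequence worth knowing: a single event on a root-child
branch is not identifiable — the change can be placed on either
root-child branch with equal parsimony. This is the ambiguity outgroup
rooting exists to resolve, and the simulation studies therefore place
designed switches only on branches where the placement is unique.

## The synthetic-data generator

The generator emulates the statistical structure of the real homologue
set — ~479-residue proteins at ~58% mean identity to the query carrying
short conserved motifs with lineage-specific variants — while keeping
every quantity's expectation in closed form:

* **Substitution model**: per branch, each site mutates with probability
  p to a uniform choice among the other 19 residues (a 20-state
  Jukes–Cantor analogue). Expected leaf-root identity after d branches
  is 1/20 + (19/20)(1 − 20p/19)^d, inverted by
  `subst_prob_for_expected_identity`. This is deliberately
  non-biological (no empirical exchangeability, no rate heterogeneity);
  it exists to give threshold and recovery tests exact ground truth, and
  passing them says nothing about fit to real substitution processes.
* **Defaults**: root length 479; p = 0.1282, the closed-form calibration
  for 58.2% expected identity over a depth-4 balanced tree (16 leaves);
  Poisson(0.5) indel events per branch with geometric mean length 3;
  20 decoys per proteome. Protected implant windows (25 of 479 residues
  under the default six-motif layout) never mutate, which biases
  realized whole-sequence identity upward by roughly two points relative
  to the substitution-only expectation; the acceptance report measures
  ~59–60% with the package's aligner.
* **Implants and switches**: implanted motif windows are excluded from
  substitutions and indels ("protected"), so ground-truth motif
  positions remain well-defined at all mutation rates; they change only
  through designated switch events on designated branches (switch texts
  must be within 2 edits of canonical). Decoy proteomes are
  composition-matched random sequences rejection-sampled against the
  query under the profiler's own thresholds.
* **Determinism**: one integer seed drives a single PCG64 stream through
  tree construction, evolution and decoy generation; identical configs
  give byte-identical outputs.

## Problem sizes in the test and acceptance studies

Scanner equivalence uses 1,000 random 500-mers × the full catalog
against a brute-force window oracle. Aligner equivalence uses all
4-letter-alphabet pairs up to length 2 exhaustively plus 300 random
pairs up to length 6 against assumption-free path enumeration, with a
Biopython `PairwiseAligner` cross-check on 200-residue pairs. Parsimony
equivalence uses 500 random binary trees (≤ 8 leaves, ≤ 3 states)
against exhaustive ancestral enumeration. The end-to-end study runs 100
seeded replicates on a balanced 8-leaf tree at ~88% expected identity
(root length 479, two designed absent proteomes, 20 decoys each, one
designed CSSC→CSSS switch, indel-free so the family doubles as its own
alignment) and demands the designed presence/absence matrix and the
switch branch back. These sizes keep the whole suite desk-scale while
exercising every code path end to end.

## Known limitations

* No alignment construction: the master alignment is an input (real
  studies build it with MAFFT and edit by hand).
* No heuristic search, E-values or composition statistics; profiling is
  exact and O(mn) per pair, so screening thousands of full proteomes is
  out of scope.
* Parsimony is unweighted and branch-length-blind; lateral-transfer
  claims are not tested statistically (incongruence counts only).
* The simulator evolves a single domain; no domain-architecture or
  codon-level realism.
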