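# Methods

## Genetic codes and subfamilies

Translation tables are the NCBI set embedded in Biopython
(ids 1–6, 9–16, 21–33; NCBI never assigned 7, 8 or 17–20). The internal
alphabet is DNA (T, not U); readers normalize U→T and uppercase on
input so RNA-style notation can be supplied anywhere. A *synonymous
subfamily* is the subset of an amino acid's codons sharing positions
1–2; `subfamilies()` returns them ordered by descending size, ties
broken lexicographically by prefix, which makes the "largest subfamily"
in the degeneration rules deterministic.

## Degeneration protocols

Both protocols first degenerate every subfamily's third position to the
IUPAC symbol covering exactly its observed third positions — by
construction a pure operation (the resolved set is the subfamily
itself).

**Principled.** For each subfamily strictly smaller than the largest:
if its prefix differs from the largest subfamily's prefix at exactly
one of positions 1–2, that position is widened to the IUPAC union of
the two prefixes there, and the merge is accepted only if every
resolved codon of the widened triplet is still synonymous (checked by
exhaustive expansion against the code table). Failing either condition,
the subfamily keeps its unambiguous prefix and the amino acid is
recorded in `incompatible_families`. Design choices where the rule is
under-determined:

* *Equal-sized subfamilies* (no "smaller" one): no merge is attempted;
  the family is flagged incompatible. The rule is defined only for
  unequal sizes.
* *More than two subfamilies*: the merge is applied pairwise between
  the largest subfamily and each smaller one independently; the purity
  check guards each merge separately.
* *Stop codons* map to themselves and form no subfamilies; flagging
  in-frame stops is translation's job, not degeneration's.

**Degen1.** If all of an amino acid's subfamilies agree at one of
positions 1–2, every codon is rewritten with, at each varying position
(including position 3), the IUPAC union over the amino acid's *full*
codon set — no purity constraint, so standard-code Leu becomes YTN,
which also resolves to Phe codons. If the subfamilies differ at both
positions 1 and 2 (standard-code Ser), each subfamily is degenerated
independently at position 3 only (TCN, AGY); published Degen1 usage
does not merge serine's classes either, but this specific reading is
our inference.

`degenerate_msa` rewrites unambiguous in-frame sense codons only; gap
triples, stop codons, and codons already containing ambiguity or
missing symbols pass through, which makes the operation idempotent.
Gaps breaking a codon, or sequence lengths not divisible by 3, raise a
frame error naming the sequence and site.

## Ambiguity-averaged scoring and SP

The base scheme defaults to match +1, transition −1, transversion −2.
`expand_matrix` fills all 120 unordered entries over the 15 IUPAC
symbols by exhaustively resolving both symbols and averaging; all
arithmetic is exact rational (`fractions.Fraction`), reported as
floats, so entries like (1−1)/2 = 0 carry no rounding.

`pair_score` treats columns as follows: residue–residue columns score
by the matrix; columns gapped in both sequences are projected out
before gap-run detection (shared gaps are never penalized and never
re-open a run); columns with missing data (`?`) on either side are
likewise projected out — missing data is no evidence for or against
homology, unlike a gap, which asserts an indel. A maximal residue–gap
run then costs gap_open for its first column and gap_extend for each
subsequent one. Runs are recomputed per sequence pair, not columnwise
across the MSA, matching the sum-of-all-pairwise-scores definition of
SP. Defaults gap_open = −5, gap_extend = −1 are conventional; every
worked scoring example in the tests is gap-free, so their values do not
depend on this choice.

`select_best_alignment` requires candidates to agree on identifiers and
ungapped content, returns the maximal-SP candidate, and breaks exact
ties toward the earliest candidate (flagged in the report).

## PWM refinement

`build_pwm` counts only unambiguous A/C/G/T; gaps, `?` and ambiguity
codes are excluded from both the per-site counts and the background.
Site counts are add-pseudocount smoothed (default 1), normalized,
divided by the background frequency and log-transformed (default base
2). The background is smoothed with the same pseudocount so the log
ratio stays finite when a base is absent from the MSA entirely; with
pseudocount 0 this reduces to the raw definition (a pure-A column over
a base-balanced alignment scores log2(1/0.25) = 2). An all-gap column
yields a zero row plus a warning.

`refine_msa` permits exactly one move type: a residue immediately
bordering a gap run in its own sequence slides to the opposite end of
that run. A move is accepted iff it strictly increases the PWM-sum
objective (sum over residues of their site PWM value); equal-objective
moves are rejected for determinism. The PWM is rebuilt once per pass,
not per move (stability and determinism; recomputing per move would
make the result depend on scan order in opaque ways); scanning is by
input sequence order, left to right, first improving move accepted and
the sequence rescanned. Within a pass the objective strictly increases
with each accepted move under the pass's fixed PWM, so each pass
terminates; passes repeat to a fixpoint or `max_iter` (default 10).

## Threading

`translate` maps gap triples to a single gap and ambiguous codons to X
unless every resolution is synonymous (YTR → L); stop codons warn, or
raise in strict mode. `thread_codons` verifies that each codon sequence
translates exactly to its degapped protein row before expanding each
amino-acid column to a codon triple and each gap to `---`; terminal
stop codons are stripped with a warning first, internal stops fail by
default (`internal_stop="warn"` downgrades). Degapping any output row
recovers the input codons exactly.

## Supermatrix, serine filter, GC3

`concatenate` unions taxa across genes in order of first appearance,
fills a taxon's missing genes with `?` (configurable to `-`; `?` keeps
missing-gene blocks distinguishable from within-alignment indels), and
optionally inserts a separator (conventionally `NNNNNN`, 6 nt so codon
frame is preserved) between gene blocks. Partition coordinates are
1-based inclusive and never include separator columns.

`serine_site_filter` removes a codon site iff at least one row carries
an AG-prefixed codon and a *different* row carries a TC-prefixed codon
— the two serine codon classes that are identical at the amino-acid
level but maximally divergent at the nucleotide level, a known source
of nucleotide-tree/protein-tree discordance. The default rule is the
literal two-nucleotide-prefix reading (so AGA/AGG, which are Arg in the
standard code, count as AGN); `strict_serine=True` restricts both sides
to codons whose sense resolutions all encode serine under the given
code (AGY vs TCN in the standard code). Both readings are defensible;
the literal one is the default and the strict one is a flag.

`gc3` is 100 × (G+C at third codon positions) / (third positions that
are not gap, `?` or N). The doubly-degenerate symbol S (G-or-C) counts
toward the numerator; other ambiguity codes count in the denominator
only. Whole-triple gaps leave the value unchanged.

## Fitch counting

Rooted strictly binary trees only; multifurcations raise rather than
being silently resolved, because arbitrary resolution changes switch
counts. Tips without a state (or scored `?`) receive the full observed
state alphabet, the standard Fitch convention. The union count of the
post-order intersection/union pass equals the parsimony length; the
test suite verifies this against an exhaustive minimum over all
internal-node state assignments for random trees up to 8 tips.

## Synthetic data generator

`make_fixture` emulates the structural features of a real multi-gene
supermatrix that this package manipulates: per-taxon GC3 targets
(default evenly spread 30–80%, the order of compositional heterogeneity
seen across deeply divergent arthropod taxa), injected AGN/UCN serine
co-occurrence sites with ground-truth counts, optional residues
displaced across a gap run, and per-gene taxon dropout (default 20%)
for concatenation tests. Defaults are 8 taxa × 60 codon sites × 3
genes — small enough to test in milliseconds while exercising every
code path. It does **not** emulate phylogenetic signal: sites are drawn
independently with no tree, no rate variation and no indel process, so
passing tests demonstrate the correctness of the matrix operations
(filtering, concatenation, threading, refinement bookkeeping), not
phylogenetic accuracy on real data. All randomness flows from one
integer seed through a single NumPy generator; identical seeds
reproduce identical bytes.

## Numerical and degenerate-input choices

* Scoring is exact rational arithmetic end to end; float conversion
  happens only at the reporting boundary.
* 1-based inclusive coordinates in all user-facing reports (partition
  tables, removed-site indices), matching NEXUS/RAxML conventions.
* Duplicate identifiers and ragged rows are rejected at `Msa`
  construction, so every downstream operation can assume a rectangle.
* An SP score or PWM is refused for fewer than two sequences; a GC3
  value with no countable third positions raises rather than returning
  a silent 0.

## Known limitations

* No aligner is included: the package scores, selects, refines and
  threads alignments produced elsewhere (`align-aa` shells out to
  MAFFT/MUSCLE if present on PATH; nothing requires them).
* PWM refinement is nucleotide-only and single-residue: it will not
  slide a block of residues as a unit, and it optimizes a greedy local
  objective, not SP.
* Degeneration assumes one genetic code per matrix; mixed-code
  supermatrices must be degenerated per partition.
* Published SP values from other programs are generally not
  reproducible without their (often unstated) gap penalties; SP
  comparisons are meaningful within one scheme, relationally.
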