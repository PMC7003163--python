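# degenphy

Codon-aware alignment and supermatrix tools for deep phylogenetics:
principled codon degeneration, ambiguity-averaged sum-of-pairs (SP)
alignment scoring, PWM-based alignment refinement, codon-onto-protein
threading, supermatrix assembly with serine AGN/UCN site filtering and
GC3 diagnostics, and Fitch parsimony state-switch counting.

It is aimed at molecular phylogeneticists assembling multi-gene
supermatrices over deeply divergent taxa, where two recurring sources of
error live upstream of tree inference: unreliable multiple sequence
alignments that are never checked for quality, and third-codon-position
homoplasy that is suppressed by codon degeneration protocols that can
themselves introduce bias.

## The methods

**Codon degeneration.** An amino acid's codons split into *synonymous
subfamilies* sharing codon positions 1–2 (standard-code Leu = the
four-codon CTN subfamily + the two-codon TTR subfamily). The widely used
Degen1 protocol merges subfamilies without constraint: all six Leu codons
become YTN. But YTN is heterogeneous — it resolves to Phe codons (TTT,
TTC) as well as Leu — so the degeneration erases the Phe/Leu distinction.
The *principled* protocol instead degenerates position 1 or 2 **only in
the smaller subfamily**, and only when the resulting class stays purely
synonymous: Leu becomes CTN + YTR. The two classes are *compatible*
(they share CTA and CTG, a single-substitution evolutionary path) while
neither overlaps another amino acid's codons. The same rule handles
non-standard codes, e.g. the Lys family {AAA, AAG, AGG} of NCBI table 24
degenerates to AAR + ARG — never ARR, which would swallow the Ser codon
AGA. Where no pure merge exists (standard-code Ser, whose subfamilies
TCN and AGY differ at both of positions 1 and 2), each subfamily is
degenerated at position 3 only and the family is flagged incompatible.

**Ambiguity-averaged SP scoring.** With a +1 match / −1 transition / −2
transversion scheme, entries for IUPAC ambiguity codes are means over
resolved pairs: entry(A, R) = (1 − 1)/2 = 0, entry(A, Y) = −2. The SP
score of an MSA is the sum of all pairwise alignment scores under this
matrix with affine gap penalties, shared gaps never penalized; among
candidate alignments of the same sequences, higher SP = better MSA.

**PWM refinement.** A position weight matrix (log of site-specific over
background frequency per nucleotide) identifies residues stranded on
the wrong side of a gap run; refinement greedily slides them across the
run when that strictly raises the total PWM propensity.

**Fitch parsimony.** On a rooted binary tree with discrete tip states,
the post-order pass takes the intersection of the two children's state
sets when nonempty, else their union; the union count is the minimum
number of state switches the tree requires (e.g. aquatic/terrestrial
habitat switches).

## Worked example

Three aligned one-codon sequences: S1 = CTC and S2 = TTG are synonymous
Leu codons; S3 = TTC is Phe.

```sh
$ printf '>S1\nCTC\n>S2\nTTG\n>S3\nTTC\n' > one_codon.fasta
$ degenphy sp --in one_codon.fasta
-1.0
$ degenphy degen --in one_codon.fasta --out principled.fasta --protocol principled
$ cat principled.fasta
>S1
CTN
>S2
YTR
>S3
TTY
```

Undegenerated, the pair scores are AS12 = −2, AS13 = 1, AS23 = 0 (SP =
−1): the two *synonymous* codons score **lower** than either
nonsynonymous pair — exactly the artifact degeneration exists to fix.
Degen1 coding flattens all three pair scores to 0, erasing the
Phe/Leu signal. The principled coding above gives AS12 = 0,
AS13 = AS23 = −1: synonymous homology now ranks above nonsynonymous, and
the amino-acid distinction survives.

Fitch counting on a habitat-scored chelicerate tree (W = aquatic,
L = terrestrial):

```sh
$ degenphy fitch --tree tree.nwk --states states.tsv
switches	1
(((Eurypterida[&states={W}],Xiphosura[&states={W}])[&states={W}],(Scorpiones[&states={L}],Tetrapulmonata[&states={L}])[&states={L}])[&states={LW}],Outgroup[&states={L}])[&states={L}];
```

Grouping the two aquatic tips (Eurypterida sister to Xiphosura) needs a
single habitat switch; placing Eurypterida sister to Scorpiones instead
forces a minimum of two.

Other subcommands: `codes`, `sp-compare`, `refine`, `thread`,
`align-aa` (external-aligner hook), `concat`, `filter-ser`, `gc3`,
`fixture`. Run `degenphy <cmd> --help` for defaults.

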