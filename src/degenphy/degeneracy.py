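"""Codon degeneration maps: the "principled" protocol and Degen1.

Both protocols rewrite each sense codon as an IUPAC-degenerate triplet
so that synonymous codons collapse toward a common representation,
suppressing compositional homoplasy at silent sites. They differ in how
compound codon families (amino acids with several subfamilies) are
handled:

* **Degen1** (Regier-style) merges subfamilies without a purity
  constraint: standard-code Leu becomes YTN throughout, a class that
  also contains Phe codons (TTT, TTC).
* The **principled** protocol degenerates position 1 or 2 only in the
  *smaller* subfamily, and only when the resulting class stays purely
  synonymous: Leu becomes CTN + YTR. CTN and YTR share codons
  (CTA, CTG) — they are *compatible*, linked by a single-substitution
  path — while neither overlaps any Phe codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from degenphy.alphabet import (
    GAP,
    expand_codon,
    is_unambiguous,
    union_symbol,
)
from degenphy.genetic_code import GeneticCode, SynonymousSubfamily, subfamilies
from degenphy.msa import Msa


@dataclass(frozen=True)
class DegenerateCodon:
    """A triplet of IUPAC symbols and its unambiguous expansion."""

    triplet: str

    def __post_init__(self) -> None:
        expand_codon(self.triplet)  # validates symbols

    @property
    def resolved_set(self) -> frozenset[str]:
        return expand_codon(self.triplet)

    def __str__(self) -> str:
        return self.triplet


@dataclass(frozen=True)
class DegenerationMap:
    """codon -> degenerate codon under one protocol for one code.

    ``incompatible_families`` lists amino acids whose subfamilies could
    not be merged into mutually compatible degenerate classes (under
    the principled protocol: standard-code Ser, whose subfamilies
    differ at both of positions 1 and 2).
    """

    code: GeneticCode
    protocol: str
    mapping: dict[str, DegenerateCodon]
    incompatible_families: frozenset[str] = field(default_factory=frozenset)

    def __getitem__(self, codon: str) -> DegenerateCodon:
        return self.mapping[codon]


def compatible(a: DegenerateCodon, b: DegenerateCodon) -> bool:
    """Two degenerate classes are compatible iff they share a codon.

    A shared codon provides a single-substitution evolutionary path
    between the two synonymous classes.
    """
    return bool(a.resolved_set & b.resolved_set)


def _positions_differing(prefix_a: str, prefix_b: str) -> list[int]:
    return [i for i in range(2) if prefix_a[i] != prefix_b[i]]


def _family_triplet(prefix: str, fam: SynonymousSubfamily) -> str:
    return prefix + fam.third_symbol


def _is_pure(triplet: str, amino_acid: str, code: GeneticCode) -> bool:
    """Every resolution of the triplet is synonymous with amino_acid."""
    return all(code.translate_codon(c) == amino_acid for c in expand_codon(triplet))


@lru_cache(maxsize=None)
def build_principled_map(code: GeneticCode) -> DegenerationMap:
    """Principled degeneration: merge only the smaller subfamily, and
    only while the merged class stays purely synonymous.

    For each amino acid: every subfamily's third position becomes the
    IUPAC symbol covering its observed third positions. Then, for each
    subfamily strictly smaller than the largest, if its prefix differs
    from the largest subfamily's prefix at exactly one of positions
    1-2, that position in the smaller subfamily is widened to the IUPAC
    union of the two prefixes there — accepted only if every resolved
    codon of the widened class is still synonymous. Otherwise the
    smaller subfamily keeps its unambiguous prefix and the amino acid
    is flagged incompatible. Subfamilies tied in size with the largest
    are never merged (the rule is defined only for unequal sizes).
    """
    mapping: dict[str, DegenerateCodon] = {}
    incompatible: set[str] = set()
    for aa in code.amino_acids:
        fams = subfamilies(code, aa)
        largest = fams[0]
        for fam in fams:
            if fam is largest or fam.size >= largest.size:
                triplet = _family_triplet(fam.prefix, fam)
                if fam is not largest:
                    incompatible.add(aa)
            else:
                diff = _positions_differing(fam.prefix, largest.prefix)
                triplet = None
                if len(diff) == 1:
                    i = diff[0]
                    merged = union_symbol({fam.prefix[i], largest.prefix[i]})
                    prefix = fam.prefix[:i] + merged + fam.prefix[i + 1:]
                    candidate = _family_triplet(prefix, fam)
                    if _is_pure(candidate, aa, code):
                        triplet = candidate
                if triplet is None:
                    triplet = _family_triplet(fam.prefix, fam)
                    incompatible.add(aa)
            for codon in fam.codons:
                mapping[codon] = DegenerateCodon(triplet)
    # stop codons map to themselves: the protocol concerns sense codons
    for codon, aa in code.codon_to_aa.items():
        if aa == "*":
            mapping[codon] = DegenerateCodon(codon)
    return DegenerationMap(
        code=code,
        protocol="principled",
        mapping=mapping,
        incompatible_families=frozenset(incompatible),
    )


@lru_cache(maxsize=None)
def build_degen1_map(code: GeneticCode) -> DegenerationMap:
    """Degen1-style degeneration: merge subfamilies without a purity
    constraint.

    If all of an amino acid's subfamilies agree at one of codon
    positions 1-2 (differ at most at the other), every codon is
    degenerated at each varying position — including position 3 — to
    the IUPAC union over the amino acid's full codon set (standard-code
    Leu -> YTN). If subfamilies differ at both positions 1 and 2
    (standard-code Ser), each subfamily is degenerated independently at
    the third position only (TCN, AGY).
    """
    mapping: dict[str, DegenerateCodon] = {}
    for aa in code.amino_acids:
        fams = subfamilies(code, aa)
        prefixes = [f.prefix for f in fams]
        shares_pos1 = len({p[0] for p in prefixes}) == 1
        shares_pos2 = len({p[1] for p in prefixes}) == 1
        if shares_pos1 or shares_pos2:
            all_codons = code.codons_for(aa)
            symbols = [union_symbol({c[i] for c in all_codons}) for i in range(3)]
            triplet = "".join(symbols)
            for codon in all_codons:
                mapping[codon] = DegenerateCodon(triplet)
        else:
            for fam in fams:
                triplet = _family_triplet(fam.prefix, fam)
                for codon in fam.codons:
                    mapping[codon] = DegenerateCodon(triplet)
    for codon, aa in code.codon_to_aa.items():
        if aa == "*":
            mapping[codon] = DegenerateCodon(codon)
    return DegenerationMap(code=code, protocol="degen1", mapping=mapping)


class FrameError(ValueError):
    """A sequence violates codon framing (length or partial-gap codon)."""


def degenerate_msa(msa: Msa, degen_map: DegenerationMap) -> Msa:
    """Apply a degeneration map codon-by-codon to an aligned matrix.

    Gap triples, codons containing ambiguity or missing symbols, and
    stop codons pass through unchanged, which makes the operation
    idempotent. Sequence lengths, identifiers and gap positions are
    preserved. Raises :class:`FrameError` for a sequence whose length
    is not a multiple of 3 or where a gap breaks a codon.
    """
    out: list[str] = []
    for rid, seq in msa.records:
        if len(seq) % 3:
            raise FrameError(f"sequence {rid!r}: length {len(seq)} not divisible by 3")
        chunks: list[str] = []
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            n_gaps = codon.count(GAP)
            if n_gaps == 3:
                chunks.append(codon)
                continue
            if n_gaps:
                raise FrameError(
                    f"sequence {rid!r}: gap breaks codon at site {i + 1} ({codon!r})"
                )
            if all(is_unambiguous(c) for c in codon):
                chunks.append(degen_map.mapping[codon].triplet)
            else:
                chunks.append(codon)  # ambiguity / missing: pass through
        out.append("".join(chunks))
    return msa.with_sequences(out)
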