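"""Genetic-code tables and synonymous codon subfamilies.

A synonymous *subfamily* is the set of an amino acid's codons sharing
their first two positions (the Leu family in the standard code splits
into the four-codon CT subfamily and the two-codon TT subfamily). An
amino acid with more than one subfamily is a *compound* codon family
(Leu, Ser, Arg in the standard code); compound families are where codon
degeneration needs care.

Tables come from the embedded NCBI translation tables shipped with
Biopython, so everything works without network access.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio.Data import CodonTable

from degenphy.alphabet import BASES, union_symbol

STOP = "*"

#: NCBI translation-table ids available in the embedded data.
SUPPORTED_TABLE_IDS: tuple[int, ...] = tuple(sorted(CodonTable.unambiguous_dna_by_id))


class UnsupportedCodeError(ValueError):
    """Raised for a translation-table id outside the embedded NCBI set."""


@dataclass(frozen=True)
class GeneticCode:
    """An NCBI translation table: all 64 codons to amino acid or stop."""

    table_id: int
    codon_to_aa: dict[str, str]
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError(f"expected 64 codons, got {len(self.codon_to_aa)}")

    def __hash__(self) -> int:  # codon_to_aa is determined by table_id
        return hash(self.table_id)

    def translate_codon(self, codon: str) -> str:
        """One-letter amino acid, or '*' for a stop codon."""
        return self.codon_to_aa[codon]

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa[codon] == STOP

    def codons_for(self, amino_acid: str) -> list[str]:
        """All codons of an amino acid, in TCAG table order."""
        return [c for c, aa in self.codon_to_aa.items() if aa == amino_acid]

    @property
    def amino_acids(self) -> list[str]:
        """Amino acids encoded by the table (stop excluded), sorted."""
        return sorted({aa for aa in self.codon_to_aa.values() if aa != STOP})


@dataclass(frozen=True)
class SynonymousSubfamily:
    """An amino acid's codons sharing codon positions 1-2."""

    amino_acid: str
    prefix: str
    third_positions: frozenset[str]

    @property
    def codons(self) -> frozenset[str]:
        return frozenset(self.prefix + b for b in self.third_positions)

    @property
    def size(self) -> int:
        return len(self.third_positions)

    @property
    def third_symbol(self) -> str:
        """IUPAC symbol covering the subfamily's third positions."""
        return union_symbol(self.third_positions)


@lru_cache(maxsize=None)
def build_code(table_id: int) -> GeneticCode:
    """Build a validated :class:`GeneticCode` for an NCBI table id.

    Raises :class:`UnsupportedCodeError` for ids absent from the NCBI
    set (e.g. the unassigned ids 7, 8, 17-20).
    """
    if table_id not in CodonTable.unambiguous_dna_by_id:
        raise UnsupportedCodeError(
            f"unsupported NCBI translation table {table_id}; "
            f"available: {list(SUPPORTED_TABLE_IDS)}"
        )
    table = CodonTable.unambiguous_dna_by_id[table_id]
    mapping: dict[str, str] = {}
    for b1 in BASES:
        for b2 in BASES:
            for b3 in BASES:
                codon = b1 + b2 + b3
                mapping[codon] = STOP if codon in table.stop_codons else table.forward_table[codon]
    return GeneticCode(table_id=table_id, codon_to_aa=mapping, name=table.names[0])


def subfamilies(code: GeneticCode, amino_acid: str) -> list[SynonymousSubfamily]:
    """Decompose an amino acid's codon set into synonymous subfamilies.

    Ordered by descending size, ties broken by prefix lexicographic
    order. Raises ValueError if the amino acid is not encoded.
    """
    codons = code.codons_for(amino_acid)
    if not codons or amino_acid == STOP:
        raise ValueError(f"amino acid {amino_acid!r} not encoded in table {code.table_id}")
    by_prefix: dict[str, set[str]] = {}
    for codon in codons:
        by_prefix.setdefault(codon[:2], set()).add(codon[2])
    fams = [
        SynonymousSubfamily(amino_acid=amino_acid, prefix=p, third_positions=frozenset(t))
        for p, t in by_prefix.items()
    ]
    fams.sort(key=lambda f: (-f.size, f.prefix))
    return fams
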