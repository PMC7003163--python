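"""IUPAC nucleotide alphabet utilities shared across the package.

The canonical internal alphabet uses T (not U); readers accept U/u and
normalize to T so that RNA- and DNA-style notation can be mixed freely
on input while a single code path handles everything downstream.
"""

from __future__ import annotations

GAP = "-"
MISSING = "?"

BASES = ("T", "C", "A", "G")

# IUPAC symbol -> frozenset of resolved bases (15 symbols, no gap).
IUPAC_TO_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

BASES_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_TO_BASES.items()}

IUPAC_SYMBOLS = tuple(IUPAC_TO_BASES)

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def normalize(seq: str) -> str:
    """Uppercase and convert U to T. '.' is accepted as a gap alias."""
    return seq.upper().replace("U", "T").replace(".", GAP)


def resolve(symbol: str) -> frozenset[str]:
    """Resolved base set of a single IUPAC symbol.

    Raises KeyError for gap/missing/unknown symbols.
    """
    return IUPAC_TO_BASES[symbol]


def union_symbol(bases) -> str:
    """The minimal IUPAC symbol covering a nonempty set of bases."""
    key = frozenset(bases)
    try:
        return BASES_TO_IUPAC[key]
    except KeyError:
        raise ValueError(f"not a valid base set: {sorted(key)}") from None


def is_unambiguous(symbol: str) -> bool:
    return symbol in ("A", "C", "G", "T")


def expand_codon(codon: str) -> frozenset[str]:
    """Cartesian expansion of a (possibly ambiguous) IUPAC triplet."""
    if len(codon) != 3:
        raise ValueError(f"not a triplet: {codon!r}")
    s1, s2, s3 = (resolve(c) for c in codon)
    return frozenset(a + b + c for a in s1 for b in s2 for c in s3)
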