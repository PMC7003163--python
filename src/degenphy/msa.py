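"""The shared alignment container and readers/writers for FASTA, PHYLIP
and NEXUS.

``Msa`` is a thin, ordered, equal-length record collection — the unit of
scoring, refinement, degeneration and concatenation throughout the
package. File I/O delegates to Bio.AlignIO; identifiers and residues
round-trip byte-for-byte modulo line wrapping.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from degenphy.alphabet import GAP, MISSING, normalize


@dataclass
class Msa:
    """Equal-length gapped sequences with unique identifiers.

    Parameters
    ----------
    records : list of (identifier, gapped sequence) pairs
    alphabet : "nucleotide" or "protein" (a tag, not enforced per-symbol)
    """

    records: list[tuple[str, str]]
    alphabet: str = "nucleotide"

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate identifiers: {dup}")
        lengths = {len(r[1]) for r in self.records}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")

    # -- basic accessors -------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.records]

    @property
    def sequences(self) -> list[str]:
        return [r[1] for r in self.records]

    @property
    def length(self) -> int:
        return len(self.records[0][1]) if self.records else 0

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, identifier: str) -> str:
        for rid, seq in self.records:
            if rid == identifier:
                return seq
        raise KeyError(identifier)

    def __contains__(self, identifier: str) -> bool:
        return identifier in self.ids

    def __iter__(self):
        return iter(self.records)

    def degapped(self, identifier: str) -> str:
        """Sequence content with gap and missing symbols removed."""
        return self[identifier].replace(GAP, "").replace(MISSING, "")

    def with_sequences(self, new_seqs: list[str]) -> "Msa":
        """Same identifiers/alphabet, replaced sequence strings."""
        return Msa(
            records=[(rid, s) for (rid, _), s in zip(self.records, new_seqs)],
            alphabet=self.alphabet,
        )


_FORMAT_MAP = {
    "fasta": "fasta",
    "phylip": "phylip-relaxed",
    "nexus": "nexus",
}

_EXT_MAP = {
    ".fa": "fasta",
    ".fas": "fasta",
    ".fasta": "fasta",
    ".phy": "phylip",
    ".phylip": "phylip",
    ".nex": "nexus",
    ".nexus": "nexus",
}


def sniff_format(path: str) -> str:
    """Guess alignment format from the file extension (default fasta)."""
    return _EXT_MAP.get(os.path.splitext(path)[1].lower(), "fasta")


def read_alignment(path: str, fmt: str | None = None, alphabet: str = "nucleotide") -> Msa:
    """Read an alignment in FASTA, relaxed PHYLIP, or NEXUS.

    Nucleotide sequences are normalized to uppercase T-alphabet (U -> T).
    Protein sequences are uppercased only.
    """
    fmt = fmt or sniff_format(path)
    if fmt not in _FORMAT_MAP:
        raise ValueError(f"unsupported format: {fmt!r} (use fasta/phylip/nexus)")
    try:
        aln = AlignIO.read(path, _FORMAT_MAP[fmt])
    except ValueError as exc:
        raise ValueError(f"cannot read {path} as {fmt}: {exc}") from exc
    records = []
    for rec in aln:
        seq = str(rec.seq)
        seq = normalize(seq) if alphabet == "nucleotide" else seq.upper()
        records.append((rec.id, seq))
    return Msa(records=records, alphabet=alphabet)


def write_alignment(msa: Msa, path: str, fmt: str | None = None) -> None:
    """Write an alignment in FASTA, relaxed PHYLIP, or NEXUS."""
    fmt = fmt or sniff_format(path)
    if fmt not in _FORMAT_MAP:
        raise ValueError(f"unsupported format: {fmt!r} (use fasta/phylip/nexus)")
    moltype = "DNA" if msa.alphabet == "nucleotide" else "protein"
    records = [
        SeqRecord(Seq(seq), id=rid, description="", annotations={"molecule_type": moltype})
        for rid, seq in msa.records
    ]
    AlignIO.write(MultipleSeqAlignment(records), path, _FORMAT_MAP[fmt])
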