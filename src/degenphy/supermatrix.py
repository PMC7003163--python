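"""Supermatrix assembly, serine AGN/UCN convergence filtering, and GC3
diagnostics.

Per-gene alignments over partially overlapping taxon sets are
concatenated into one matrix, with a taxon's missing genes filled as
missing data and a partition table recording each gene's coordinates.
Serine is the one standard-code amino acid encoded by two codon classes
(AGY and TCN) that are identical at the amino-acid level yet maximally
divergent at the nucleotide level; codon sites where both classes
co-occur across taxa inject convergence noise into nucleotide-based
trees and can be filtered out. GC content at third codon positions
(GC3) flags compositional convergence across taxa.
"""

from __future__ import annotations

from dataclasses import dataclass

from degenphy.alphabet import GAP, MISSING
from degenphy.degeneracy import FrameError
from degenphy.genetic_code import GeneticCode
from degenphy.msa import Msa


@dataclass(frozen=True)
class Partition:
    """A gene block's 1-based inclusive coordinates in the supermatrix.

    Coordinates exclude any separator columns; for codon data the span
    is a multiple of 3.
    """

    name: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def concatenate(
    gene_msas: list[tuple[str, Msa]],
    separator: str | None = "NNNNNN",
    missing_fill: str = MISSING,
) -> tuple[Msa, list[Partition]]:
    """Concatenate per-gene alignments into a supermatrix.

    The row set is the union of identifiers across genes (order of
    first appearance); a taxon absent from a gene receives
    ``missing_fill`` over that gene's aligned length. The separator
    (conventionally ``NNNNNN``, or None for none) is inserted between
    gene blocks in every row but never counted in partition
    coordinates. Raises ValueError for a gene with internally unequal
    row lengths (caught by Msa) or duplicate identifiers.
    """
    sep = separator or ""
    taxa: list[str] = []
    for _, msa in gene_msas:
        for rid in msa.ids:
            if rid not in taxa:
                taxa.append(rid)
    rows: dict[str, list[str]] = {t: [] for t in taxa}
    partitions: list[Partition] = []
    pos = 0  # 0-based running coordinate including separators
    for k, (name, msa) in enumerate(gene_msas):
        if k > 0:
            for t in taxa:
                rows[t].append(sep)
            pos += len(sep)
        glen = msa.length
        partitions.append(Partition(name=name, start=pos + 1, end=pos + glen))
        for t in taxa:
            rows[t].append(msa[t] if t in msa else missing_fill * glen)
        pos += glen
    super_msa = Msa(
        records=[(t, "".join(rows[t])) for t in taxa],
        alphabet=gene_msas[0][1].alphabet if gene_msas else "nucleotide",
    )
    return super_msa, partitions


def write_partitions(partitions: list[Partition], path: str, datatype: str = "DNA") -> None:
    """Write a RAxML-style partition file (1-based inclusive ranges)."""
    with open(path, "w") as fh:
        for p in partitions:
            fh.write(f"{datatype}, {p.name} = {p.start}-{p.end}\n")


def _codon_at(seq: str, site: int) -> str:
    return seq[3 * site : 3 * site + 3]


def _is_agn(codon: str, code: GeneticCode | None, strict: bool) -> bool:
    if not codon.startswith("AG"):
        return False
    if not strict:
        return True
    return _all_sense_resolutions_serine(codon, code)


def _is_ucn(codon: str, code: GeneticCode | None, strict: bool) -> bool:
    if not codon.startswith("TC"):
        return False
    if not strict:
        return True
    return _all_sense_resolutions_serine(codon, code)


def _all_sense_resolutions_serine(codon: str, code: GeneticCode) -> bool:
    from degenphy.alphabet import expand_codon, is_unambiguous

    if any(not is_unambiguous(c) and c not in "RYSWKMBDHVN" for c in codon):
        return False  # gaps / missing in codon
    resolved = expand_codon(codon)
    sense = [c for c in resolved if not code.is_stop(c)]
    return bool(sense) and all(code.translate_codon(c) == "S" for c in sense)


def serine_site_filter(
    codon_msa: Msa,
    code: GeneticCode | None = None,
    strict_serine: bool = False,
) -> tuple[Msa, int, list[int]]:
    """Remove codon sites where AGN and UCN codons co-occur.

    A codon site (triple of columns) is removed iff at least one row
    carries an AG-prefixed codon and at least one *other* row carries a
    TC-prefixed codon. The default applies the two-nucleotide-prefix
    rule literally; ``strict_serine`` restricts it to codons all of
    whose sense resolutions encode serine under ``code`` (AGY vs TCN in
    the standard code). Returns the filtered MSA, the removed-site
    count, and the 1-based codon-site indices removed.
    """
    if strict_serine and code is None:
        raise ValueError("strict_serine requires a genetic code")
    if codon_msa.length % 3:
        raise FrameError(f"alignment length {codon_msa.length} not divisible by 3")
    n_sites = codon_msa.length // 3
    removed: list[int] = []
    for site in range(n_sites):
        agn_rows = set()
        ucn_rows = set()
        for r, (_, seq) in enumerate(codon_msa.records):
            codon = _codon_at(seq, site)
            if _is_agn(codon, code, strict_serine):
                agn_rows.add(r)
            if _is_ucn(codon, code, strict_serine):
                ucn_rows.add(r)
        # co-occurrence must involve two distinct rows
        if agn_rows and ucn_rows and len(agn_rows | ucn_rows) >= 2:
            removed.append(site + 1)
    removed_set = set(removed)
    new_seqs = [
        "".join(
            _codon_at(seq, site)
            for site in range(n_sites)
            if site + 1 not in removed_set
        )
        for _, seq in codon_msa.records
    ]
    return codon_msa.with_sequences(new_seqs), len(removed), removed


def gc3(codon_seq: str) -> float:
    """GC percentage at third codon positions.

    The denominator counts third positions that are not gap, missing,
    or fully ambiguous N; S (G-or-C) counts toward the numerator.
    Raises ValueError when no third position is countable.
    """
    if len(codon_seq) % 3:
        raise FrameError(f"length {len(codon_seq)} not divisible by 3")
    thirds = codon_seq[2::3].upper().replace("U", "T")
    countable = [c for c in thirds if c not in (GAP, MISSING, "N")]
    if not countable:
        raise ValueError("no countable third codon positions")
    gc = sum(1 for c in countable if c in "GCS")
    return 100.0 * gc / len(countable)
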