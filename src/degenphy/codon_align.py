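"""Translation and codon-onto-protein threading.

Codon sequences for divergent taxa are best aligned indirectly:
translate, align the amino-acid sequences, then map each codon sequence
back onto its aligned protein row so that every amino-acid column
expands to a codon triple and every gap to ``---``. This keeps the
nucleotide alignment in frame and congruent with protein homology.
"""

from __future__ import annotations

import warnings

from degenphy.alphabet import GAP, MISSING, expand_codon, is_unambiguous, normalize
from degenphy.degeneracy import FrameError
from degenphy.genetic_code import STOP, GeneticCode
from degenphy.msa import Msa


def translate(codon_seq: str, code: GeneticCode, strict: bool = False) -> str:
    """Translate a frame-valid (possibly gapped) nucleotide sequence.

    Gap triples become a single gap; a codon containing missing data or
    ambiguity becomes 'X' unless every resolution is synonymous (then
    that amino acid); a stop codon becomes '*' with a warning, or an
    error when ``strict`` is set.
    """
    seq = normalize(codon_seq)
    if len(seq) % 3:
        raise FrameError(f"length {len(seq)} not divisible by 3")
    out = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        n_gaps = codon.count(GAP)
        if n_gaps == 3:
            out.append(GAP)
            continue
        if n_gaps:
            raise FrameError(f"gap breaks codon at site {i + 1} ({codon!r})")
        if MISSING in codon:
            out.append("X")
            continue
        if all(is_unambiguous(c) for c in codon):
            aa = code.translate_codon(codon)
        else:
            translations = {code.translate_codon(c) for c in expand_codon(codon)}
            aa = translations.pop() if len(translations) == 1 else "X"
        if aa == STOP:
            if strict:
                raise ValueError(f"stop codon {codon} at site {i + 1}")
            warnings.warn(f"stop codon {codon} at site {i + 1}", stacklevel=2)
        out.append(aa)
    return "".join(out)


def _strip_terminal_stop(seq: str, code: GeneticCode) -> str:
    if len(seq) >= 3 and len(seq) % 3 == 0:
        last = seq[-3:]
        if all(is_unambiguous(c) for c in last) and code.is_stop(last):
            warnings.warn(f"terminal stop codon {last} stripped", stacklevel=3)
            return seq[:-3]
    return seq


def thread_codons(
    aa_alignment: Msa,
    codon_seqs: dict[str, str],
    code: GeneticCode,
    internal_stop: str = "fail",
) -> Msa:
    """Thread ungapped codon sequences onto an amino-acid alignment.

    Each amino-acid column expands to its codon triple and each gap to
    ``---``; the output length is three times the protein alignment
    length and degapping any output row recovers the input codon
    sequence exactly. Terminal stop codons are stripped with a warning
    before threading; an internal stop fails by default
    (``internal_stop="warn"`` downgrades it).

    Raises KeyError for an identifier missing from ``codon_seqs`` and
    ValueError when a codon sequence does not translate to its protein
    row.
    """
    if internal_stop not in ("fail", "warn"):
        raise ValueError("internal_stop must be 'fail' or 'warn'")
    out_records = []
    for rid, aa_row in aa_alignment.records:
        if rid not in codon_seqs:
            raise KeyError(f"identifier {rid!r} missing from codon sequences")
        nt = _strip_terminal_stop(normalize(codon_seqs[rid]), code)
        if GAP in nt:
            raise ValueError(f"codon sequence for {rid!r} must be ungapped")
        aa_from_nt = translate(nt, code, strict=(internal_stop == "fail"))
        aa_degapped = aa_row.replace(GAP, "").replace(MISSING, "")
        if aa_from_nt != aa_degapped:
            for k, (a, b) in enumerate(zip(aa_from_nt, aa_degapped)):
                if a != b:
                    raise ValueError(
                        f"translation mismatch for {rid!r} at residue {k + 1}: "
                        f"codons give {a!r}, alignment has {b!r}"
                    )
            raise ValueError(
                f"translation length mismatch for {rid!r}: "
                f"{len(aa_from_nt)} codons vs {len(aa_degapped)} residues"
            )
        chunks = []
        pos = 0
        for aa in aa_row:
            if aa == GAP or aa == MISSING:
                chunks.append(GAP * 3)
            else:
                chunks.append(nt[pos : pos + 3])
                pos += 3
        out_records.append((rid, "".join(chunks)))
    missing_ids = set(codon_seqs) - set(aa_alignment.ids)
    if missing_ids:
        raise KeyError(f"identifiers absent from the protein alignment: {sorted(missing_ids)}")
    return Msa(records=out_records, alphabet="nucleotide")
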