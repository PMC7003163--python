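"""Position-weight-matrix alignment refinement.

A PWM row holds, for each alignment site and nucleotide, the log ratio
of the site-specific frequency over the background frequency: zero
means the nucleotide is neither preferred nor avoided at that site,
positive preferred, negative avoided. Refinement greedily slides
residues that border a gap run in their own sequence to the opposite
end of the run whenever doing so strictly raises the total PWM
propensity of the alignment — the typical fix is a residue stranded on
the wrong side of a gap block by a progressive aligner.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from degenphy.alphabet import GAP
from degenphy.msa import Msa

_ALPHABET = ("A", "C", "G", "T")
_INDEX = {b: i for i, b in enumerate(_ALPHABET)}


@dataclass(frozen=True)
class Pwm:
    """Per-site, per-nucleotide log propensities over an alignment.

    values[j, i] = log(smoothed site frequency of base i at site j /
    background frequency of base i). Only unambiguous A,C,G,T are
    counted; gaps, missing symbols and ambiguity codes are excluded
    from both site counts and the background.
    """

    values: np.ndarray  # shape (n_sites, 4), columns in A,C,G,T order
    background: np.ndarray  # shape (4,)
    pseudocount: float
    log_base: float

    def value(self, site: int, symbol: str) -> float:
        """PWM value for a 0-based site and an unambiguous base."""
        return float(self.values[site, _INDEX[symbol]])


def build_pwm(msa: Msa, pseudocount: float = 1.0, log_base: float = 2.0) -> Pwm:
    """Build a PWM from a nucleotide alignment.

    Per-site counts are add-pseudocount smoothed, converted to
    frequencies over non-gap residues, divided by the background
    frequency (itself computed over all non-gap residues of the MSA and
    smoothed identically), then log-transformed. An all-gap column
    yields a row of zeros with a warning.
    """
    if len(msa) < 2:
        raise ValueError("PWM requires at least 2 sequences")
    n_sites = msa.length
    counts = np.zeros((n_sites, 4))
    for _, seq in msa.records:
        for j, sym in enumerate(seq):
            i = _INDEX.get(sym)
            if i is not None:
                counts[j, i] += 1

    bg_counts = counts.sum(axis=0) + pseudocount
    background = bg_counts / bg_counts.sum()

    values = np.zeros((n_sites, 4))
    empty = counts.sum(axis=1) == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} all-gap column(s); their PWM rows are zero",
            stacklevel=2,
        )
    occupied = ~empty
    site_counts = counts[occupied] + pseudocount
    site_freqs = site_counts / site_counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore"):  # -inf for zero freq at pseudocount 0
        values[occupied] = np.log(site_freqs / background) / math.log(log_base)
    return Pwm(values=values, background=background, pseudocount=pseudocount, log_base=log_base)


def _slide_moves(seq: str):
    """Yield (res_idx, target_idx) for residues bordering a gap run.

    A residue immediately left of a gap run may slide to the run's
    right end; a residue immediately right of a run may slide to its
    left end. Gap runs are maximal within the one sequence.
    """
    n = len(seq)
    j = 0
    while j < n:
        if seq[j] == GAP:
            start = j
            while j < n and seq[j] == GAP:
                j += 1
            end = j - 1  # inclusive
            if start > 0 and seq[start - 1] != GAP:
                yield start - 1, end  # slide rightward across the run
            if j < n and seq[j] != GAP:
                yield j, start  # slide leftward across the run
        else:
            j += 1


def refine_msa(
    msa: Msa,
    max_iter: int = 10,
    pseudocount: float = 1.0,
    log_base: float = 2.0,
) -> tuple[Msa, int]:
    """Greedy PWM refinement; returns the refined MSA and the number of
    accepted moves.

    The only move permitted slides a residue bordering a gap run in its
    own sequence to the opposite end of that run. A move is accepted
    iff it strictly increases the PWM-sum objective (the sum over all
    residues of their site PWM value); ties never move. The PWM is
    rebuilt once per pass; passes repeat until a fixpoint or
    ``max_iter``. Ungapped content and alignment length are unchanged.
    """
    seqs = list(msa.sequences)
    total_moves = 0
    for _ in range(max_iter):
        pwm = build_pwm(msa.with_sequences(seqs), pseudocount=pseudocount, log_base=log_base)
        moved_this_pass = 0
        for s_idx in range(len(seqs)):
            changed = True
            while changed:
                changed = False
                seq = seqs[s_idx]
                for res_idx, target_idx in _slide_moves(seq):
                    sym = seq[res_idx]
                    if sym not in _INDEX:
                        continue  # ambiguity codes carry no PWM value
                    delta = pwm.value(target_idx, sym) - pwm.value(res_idx, sym)
                    if delta > 0:
                        chars = list(seq)
                        chars[res_idx] = GAP
                        chars[target_idx] = sym
                        seqs[s_idx] = "".join(chars)
                        moved_this_pass += 1
                        changed = True
                        break  # rescan this sequence after the move
        total_moves += moved_this_pass
        if moved_this_pass == 0:
            break
    return msa.with_sequences(seqs), total_moves
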