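"""Ambiguity-averaged match/mismatch scoring and sum-of-pairs MSA
evaluation.

The base scheme scores a matched site +1, a transitional difference -1
and a transversional difference -2. The scheme is expanded over all 15
IUPAC nucleotide symbols by averaging across resolved base pairs: an
A/R site is either an A/A match (+1) or an A/G transition (-1), so its
entry is (1 - 1)/2 = 0, while an A/Y site is always a transversion
(-2). The sum-of-pairs (SP) score of an MSA — the sum of all pairwise
alignment scores under this matrix with affine gap penalties, shared
gaps never penalized — serves as an alignment-quality proxy: a larger
SP score means a better MSA.

Scores are exact rationals internally (averages of small integers) and
are reported as floats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations

from degenphy.alphabet import GAP, IUPAC_SYMBOLS, MISSING, PURINES, resolve
from degenphy.msa import Msa


@dataclass(frozen=True)
class ScoreScheme:
    """Base match/transition/transversion scores and affine gap costs.

    The gap penalties behind published SP values vary between programs;
    the defaults here (open -5, extend -1) are conventional and fully
    configurable.
    """

    match: float = 1.0
    transition: float = -1.0
    transversion: float = -2.0
    gap_open: float = -5.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if not (self.match > self.transition >= self.transversion):
            warnings.warn(
                "unusual scheme: expected match > transition >= transversion",
                stacklevel=3,
            )

    def base_score(self, x: str, y: str) -> Fraction:
        """Score of an unambiguous base pair."""
        if x == y:
            return Fraction(self.match)
        if (x in PURINES) == (y in PURINES):
            return Fraction(self.transition)
        return Fraction(self.transversion)


@dataclass(frozen=True)
class AmbiguityMatrix:
    """Symmetric 15x15 score table over the IUPAC nucleotide symbols.

    entry(X, Y) is the arithmetic mean of the base scores over all
    resolved pairs (x in X, y in Y); restricted to A,C,G,T it
    reproduces the base scheme exactly.
    """

    scheme: ScoreScheme
    entries: dict[frozenset[str], Fraction]

    def entry(self, x: str, y: str) -> Fraction:
        try:
            return self.entries[frozenset((x, y))]
        except KeyError:
            bad = x if x not in IUPAC_SYMBOLS else y
            raise KeyError(f"not an IUPAC nucleotide symbol: {bad!r}") from None

    def __call__(self, x: str, y: str) -> float:
        return float(self.entry(x, y))


def expand_matrix(scheme: ScoreScheme) -> AmbiguityMatrix:
    """Expand a base scheme over IUPAC symbols by exhaustive averaging."""
    entries: dict[frozenset[str], Fraction] = {}
    for x in IUPAC_SYMBOLS:
        for y in IUPAC_SYMBOLS:
            key = frozenset((x, y))
            if key in entries:
                continue
            pairs = [(a, b) for a in resolve(x) for b in resolve(y)]
            total = sum((scheme.base_score(a, b) for a, b in pairs), Fraction(0))
            entries[key] = total / len(pairs)
    return AmbiguityMatrix(scheme=scheme, entries=entries)


def _pair_score_exact(
    s1: str, s2: str, matrix: AmbiguityMatrix, scheme: ScoreScheme
) -> Fraction:
    if len(s1) != len(s2):
        raise ValueError(f"unequal lengths: {len(s1)} vs {len(s2)}")
    # project out shared-gap columns (never penalized) and columns with
    # missing data on either side ('?' carries no evidence either way);
    # neither interrupts a gap run in the projected pair
    cols = [
        (a, b)
        for a, b in zip(s1, s2)
        if not ((a == GAP and b == GAP) or a == MISSING or b == MISSING)
    ]
    score = Fraction(0)
    in_gap1 = in_gap2 = False
    for i, (a, b) in enumerate(cols):
        a_gap = a == GAP
        b_gap = b == GAP
        if a_gap:
            score += Fraction(scheme.gap_extend if in_gap1 else scheme.gap_open)
            in_gap1, in_gap2 = True, False
        elif b_gap:
            score += Fraction(scheme.gap_extend if in_gap2 else scheme.gap_open)
            in_gap1, in_gap2 = False, True
        else:
            in_gap1 = in_gap2 = False
            try:
                score += matrix.entry(a, b)
            except KeyError as exc:
                raise ValueError(f"non-IUPAC symbol at column {i + 1}: {exc}") from None
    return score


def pair_score(
    s1: str,
    s2: str,
    matrix: AmbiguityMatrix | None = None,
    scheme: ScoreScheme | None = None,
) -> float:
    """Alignment score of an aligned sequence pair.

    Residue-residue columns score by the ambiguity matrix; columns
    gapped in both sequences contribute 0; a maximal residue-gap run is
    penalized gap_open for its first column and gap_extend thereafter.
    """
    scheme = scheme or (matrix.scheme if matrix is not None else ScoreScheme())
    matrix = matrix if matrix is not None else expand_matrix(scheme)
    return float(_pair_score_exact(s1, s2, matrix, scheme))


def sp_score(msa: Msa, scheme: ScoreScheme | None = None) -> float:
    """Sum-of-pairs score: the sum of all pairwise alignment scores."""
    if len(msa) < 2:
        raise ValueError("SP score requires at least 2 sequences")
    scheme = scheme or ScoreScheme()
    matrix = expand_matrix(scheme)
    total = sum(
        (_pair_score_exact(a, b, matrix, scheme)
         for (_, a), (_, b) in combinations(msa.records, 2)),
        Fraction(0),
    )
    return float(total)


@dataclass(frozen=True)
class SelectionReport:
    """Per-candidate SP scores and the index of the winner."""

    scores: tuple[float, ...]
    best_index: int
    tie: bool


def select_best_alignment(
    candidates: list[Msa], scheme: ScoreScheme | None = None
) -> tuple[Msa, SelectionReport]:
    """Pick the candidate alignment with the highest SP score.

    All candidates must carry the same identifiers with identical
    ungapped content (they are alternative alignments of the same
    sequences). Exact ties go to the earliest candidate, flagged in the
    report.
    """
    if not candidates:
        raise ValueError("no candidate alignments")
    ref = candidates[0]
    ref_ids = set(ref.ids)
    for cand in candidates[1:]:
        if set(cand.ids) != ref_ids:
            raise ValueError("candidates disagree on sequence identifiers")
        for rid in ref_ids:
            if cand.degapped(rid) != ref.degapped(rid):
                raise ValueError(f"candidates disagree on ungapped content of {rid!r}")
    scores = tuple(sp_score(c, scheme) for c in candidates)
    best = max(range(len(scores)), key=lambda i: (scores[i], -i))
    tie = scores.count(scores[best]) > 1
    return candidates[best], SelectionReport(scores=scores, best_index=best, tie=tie)
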