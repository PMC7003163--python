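from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from degenphy.alphabet import IUPAC_SYMBOLS, resolve
from degenphy.ambig_score import (
    ScoreScheme,
    expand_matrix,
    pair_score,
    select_best_alignment,
    sp_score,
)
from degenphy.msa import Msa


def brute_force_entry(scheme, x, y):
    """Independent oracle: explicit mean over resolved base pairs."""
    pairs = [(a, b) for a in resolve(x) for b in resolve(y)]
    total = Fraction(0)
    for a, b in pairs:
        if a == b:
            total += Fraction(scheme.match)
        elif {a, b} <= set("AG") or {a, b} <= set("CT"):
            total += Fraction(scheme.transition)
        else:
            total += Fraction(scheme.transversion)
    return total / len(pairs)


@pytest.mark.parametrize(
    "x, y, expected",
    [
        ("A", "R", 0),    # (1 - 1)/2
        ("A", "Y", -2),   # always a transversion
        ("A", "A", 1),
        ("A", "G", -1),
        ("C", "T", -1),
        ("A", "C", -2),
        ("N", "N", -1),
        ("R", "Y", -2),
        ("Y", "Y", 0),
        ("C", "Y", 0),
    ],
)
def test_default_matrix_entries(default_matrix, x, y, expected):
    assert default_matrix.entry(x, y) == expected


def test_matrix_symmetric_and_complete(default_matrix):
    for x in IUPAC_SYMBOLS:
        for y in IUPAC_SYMBOLS:
            assert default_matrix.entry(x, y) == default_matrix.entry(y, x)


@settings(max_examples=25, deadline=None)
@given(
    match=st.integers(-3, 5),
    ts=st.integers(-5, 3),
    tv=st.integers(-6, 3),
)
def test_matrix_equals_brute_force_oracle_any_scheme(match, ts, tv):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scheme = ScoreScheme(match=match, transition=ts, transversion=tv)
    matrix = expand_matrix(scheme)
    for x in IUPAC_SYMBOLS:
        for y in IUPAC_SYMBOLS:
            assert matrix.entry(x, y) == brute_force_entry(scheme, x, y)


@pytest.mark.parametrize(
    "s1, s2, expected",
    [
        ("CTC", "TTG", -2),  # ts + match + tv
        ("CTC", "TTC", 1),
        ("TTG", "TTC", 0),
        ("CTN", "TTY", -1),
        ("CTN", "YTR", 0),
        ("YTR", "TTY", -1),
        ("YTN", "YTN", 0),
        ("YTN", "TTY", 0),
    ],
)
def test_pair_score_worked_examples(default_matrix, s1, s2, expected):
    assert pair_score(s1, s2, default_matrix) == expected


def test_pair_score_identity_and_symmetry(default_matrix, default_scheme):
    assert pair_score("ACGTACGT", "ACGTACGT", default_matrix) == 8 * default_scheme.match
    for a, b in [("CTC", "TTG"), ("AC-GT", "ACGGT"), ("RYN", "ACG")]:
        assert pair_score(a, b, default_matrix) == pair_score(b, a, default_matrix)


def test_pair_score_affine_gap_runs(default_matrix, default_scheme):
    # one 2-column gap run: open + extend; flanked matches
    expected = 2 * default_scheme.match + default_scheme.gap_open + default_scheme.gap_extend
    assert pair_score("A--T", "ACGT", default_matrix) == expected
    # two separate 1-column runs in opposite sequences: two opens
    assert (
        pair_score("A-GT", "ACG-", default_matrix)
        == 2 * default_scheme.match + 2 * default_scheme.gap_open
    )


def test_pair_score_shared_gaps_free(default_matrix):
    base = pair_score("ACT", "ACT", default_matrix)
    assert pair_score("AC--T", "AC--T", default_matrix) == base
    # a shared-gap column inside a run does not re-open the run
    assert pair_score("A---T", "AC--T", default_matrix) == pair_score(
        "A-T", "ACT", default_matrix
    )


def test_pair_score_missing_data_is_no_evidence(default_matrix):
    assert pair_score("A?T", "ACT", default_matrix) == pair_score("AT", "AT", default_matrix)


def test_pair_score_errors(default_matrix):
    with pytest.raises(ValueError, match="lengths"):
        pair_score("ACG", "AC", default_matrix)
    with pytest.raises(ValueError, match="column 2"):
        pair_score("AZG", "ACG", default_matrix)


def test_match_score_monotonicity_gap_free():
    s1, s2 = "ACGTRYACGG", "TCGARYACGT"
    scores = []
    for match in (1, 2, 3):
        scheme = ScoreScheme(match=match)
        scores.append(pair_score(s1, s2, expand_matrix(scheme), scheme))
    assert scores == sorted(scores)


def test_sp_score_worked_example(one_codon_msa):
    assert sp_score(one_codon_msa) == -1  # -2 + 1 + 0


def test_sp_score_two_sequences_equals_pair(default_matrix):
    msa = Msa([("a", "ACG-T"), ("b", "ATGCT")])
    assert sp_score(msa) == pair_score("ACG-T", "ATGCT", default_matrix)


def test_sp_score_all_gap_column_free(one_codon_msa):
    padded = Msa([(rid, seq + "-") for rid, seq in one_codon_msa.records])
    assert sp_score(padded) == sp_score(one_codon_msa)


def test_sp_score_matches_naive_double_loop(default_matrix):
    seqs = [("a", "ACGT-CTC"), ("b", "AC-TTCTG"), ("c", "ACGTTC--"), ("d", "?CGTTCTC")]
    msa = Msa(seqs)
    oracle = 0.0
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            oracle += pair_score(seqs[i][1], seqs[j][1], default_matrix)
    assert sp_score(msa) == pytest.approx(oracle)


def test_sp_score_needs_two_sequences():
    with pytest.raises(ValueError):
        sp_score(Msa([("a", "ACGT")]))


def test_select_best_alignment_relational():
    """Between two alignments of the same sequences, the one restoring
    homologous columns scores higher and is chosen."""
    good = Msa([("a", "ACGTT"), ("b", "ACGTT"), ("c", "ACG-T")])
    bad = Msa([("a", "ACGTT"), ("b", "ACGTT"), ("c", "A-CGT")])
    chosen, report = select_best_alignment([bad, good])
    assert chosen is good
    assert report.best_index == 1
    assert report.scores[1] > report.scores[0]
    assert not report.tie


def test_select_best_single_and_tie():
    only = Msa([("a", "ACG"), ("b", "ACG")])
    chosen, report = select_best_alignment([only])
    assert chosen is only
    dup = Msa([("a", "ACG"), ("b", "ACG")])
    chosen, report = select_best_alignment([only, dup])
    assert chosen is only  # first in input order
    assert report.tie


def test_select_best_rejects_content_mismatch():
    a = Msa([("x", "ACG"), ("y", "ACG")])
    b = Msa([("x", "ACT"), ("y", "ACG")])
    with pytest.raises(ValueError, match="x"):
        select_best_alignment([a, b])
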