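"""Global alignment, PID statistic, MSA projection and threshold arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_force_global_score
from uscg._alphabet import AA, BLOSUM62, encode
from uscg.align_pid import (aggregate_pair_pid, compute_pid, global_align,
                            min_varied_positions, project_pair_from_msa)

PROTEIN = st.text(alphabet=AA, min_size=1, max_size=7)


def test_self_alignment_is_gapless_diagonal():
    s = "MKTAYIAKQR"
    res = global_align(s, s)
    assert res.aligned_a == res.aligned_b == s
    assert res.indel_positions == 0 and res.matches == len(s)
    expected = sum(BLOSUM62[e, e] for e in encode(s))
    assert res.score == pytest.approx(expected)


def test_single_residue_match_scores_blosum_entry():
    res = global_align("A", "A")
    assert res.score == 4.0 and res.matches == 1


def test_known_pair_matches_enumeration_oracle_value():
    # brute-force enumeration over all gapped alignments of this pair gives 1.0
    res = global_align("HEAGAWGHEE", "PAWHEAE")
    assert res.score == pytest.approx(1.0)
    assert res.matches + res.mismatches + res.indel_positions == len(res.aligned_a)


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        global_align("", "A")


@settings(derandomize=True, max_examples=40, deadline=None)
@given(a=PROTEIN, b=PROTEIN)
def test_global_score_agrees_with_brute_force(a, b):
    """DP optimum equals exhaustive-enumeration optimum on small instances."""
    assert global_align(a, b, 5.0, 1.0).score == pytest.approx(
        brute_force_global_score(a, b, 5.0, 1.0))


def test_global_score_agrees_with_independent_aligner():
    """Scores match Biopython's PairwiseAligner on random realistic pairs."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -12.0    # open 11 + extend 1 for the first residue
    aligner.extend_gap_score = -1.0
    rng = np.random.default_rng(7)
    for _ in range(15):
        n, m = rng.integers(10, 60, size=2)
        a = "".join(rng.choice(list(AA), size=n))
        b = "".join(rng.choice(list(AA), size=m))
        assert global_align(a, b).score == pytest.approx(aligner.score(a, b))


# ---------------------------------------------------------------------------
# MSA projection
# ---------------------------------------------------------------------------

def test_projection_noop_without_shared_gaps():
    msa = ["AC-G", "A-CG", "ACCG"]
    assert project_pair_from_msa(msa, 0, 2) == ("AC-G", "ACCG")


def test_projection_removes_both_gap_columns():
    msa = ["A-C", "A-C", "AGC"]
    assert project_pair_from_msa(msa, 0, 1) == ("AC", "AC")


def test_projection_equals_column_scan_on_random_msa():
    rng = np.random.default_rng(5)
    alphabet = list(AA) + ["-"] * 8
    msa = ["".join(rng.choice(alphabet, size=30)) for _ in range(5)]
    for i in range(5):
        for j in range(i + 1, 5):
            got = project_pair_from_msa(msa, i, j)
            cols = [(a, b) for a, b in zip(msa[i], msa[j]) if not (a == "-" and b == "-")]
            assert got == ("".join(a for a, _ in cols), "".join(b for _, b in cols))


# ---------------------------------------------------------------------------
# PID
# ---------------------------------------------------------------------------

def test_pid_identity_and_forced_arithmetic():
    assert compute_pid("ACDE", "ACDE").pid_pct == 100.0
    assert compute_pid("ACDE", "ACDF").pid_pct == 75.0


def test_pid_at_paper_threshold_boundary():
    a = "A" * 200
    b = "A" * 199 + "C"
    assert compute_pid(a, b).pid_pct == pytest.approx(99.5)


def test_pid_counts_indels_in_denominator():
    stats = compute_pid("AC-E", "ACDE")
    assert (stats.matches, stats.mismatches, stats.indel_positions) == (3, 0, 1)
    assert stats.pid_pct == 75.0


def test_pid_case_insensitive_and_x_matches_x():
    assert compute_pid("acXe", "ACXE").pid_pct == 100.0


def test_pid_zero_length_is_missing():
    assert compute_pid("--", "--") is None


@settings(derandomize=True, max_examples=50)
@given(s=st.text(alphabet=AA + "-", min_size=1, max_size=20),
       t=st.text(alphabet=AA + "-", min_size=1, max_size=20))
def test_pid_is_symmetric(s, t):
    n = min(len(s), len(t))
    sa, sb = s[:n], t[:n]
    ra, rb = compute_pid(sa, sb), compute_pid(sb, sa)
    assert (ra is None) == (rb is None)
    if ra is not None:
        assert ra.pid_pct == rb.pid_pct
        assert ra.aligned_length == rb.aligned_length


@settings(derandomize=True, max_examples=50)
@given(s=st.text(alphabet=AA, min_size=1, max_size=20))
def test_pid_of_identical_gapfree_sequence_is_100(s):
    assert compute_pid(s, s).pid_pct == 100.0


def test_projection_then_pid_counts_every_remaining_column():
    msa = ["AC--GT-A", "A-C-G--A", "ACCTGTTA"]
    a, b = project_pair_from_msa(msa, 0, 1)
    stats = compute_pid(a, b)
    assert stats.aligned_length == len(a)


# ---------------------------------------------------------------------------
# Aggregation and the varied-positions threshold
# ---------------------------------------------------------------------------

def test_aggregate_concat_is_length_weighted():
    pair1 = ("A" * 90 + "C" * 10, "A" * 90 + "D" * 10)        # PID 90, len 100
    pair2 = ("A" * 300, "A" * 300)                            # PID 100, len 300
    assert aggregate_pair_pid([pair1, pair2]) == pytest.approx(97.5)
    equal = [("A" * 90 + "C" * 10, "A" * 90 + "D" * 10),
             ("A" * 100, "A" * 100)]
    assert aggregate_pair_pid(equal) == pytest.approx(95.0)
    assert aggregate_pair_pid([("AAAA", "AAAA")]) == 100.0


def test_aggregate_mean_mode_unweighted():
    pairs = [("A" * 90 + "C" * 10, "A" * 90 + "D" * 10), ("A" * 300, "A" * 300)]
    assert aggregate_pair_pid(pairs, mode="mean") == pytest.approx(95.0)


def test_aggregate_lies_between_min_and_max_marker_pid():
    rng = np.random.default_rng(3)
    pairs = []
    pids = []
    for _ in range(6):
        n = int(rng.integers(20, 80))
        a = "".join(rng.choice(list(AA), size=n))
        b = "".join(c if rng.random() > 0.2 else "W" for c in a)
        pairs.append((a, b))
        pids.append(compute_pid(a, b).pid_pct)
    agg = aggregate_pair_pid(pairs)
    assert min(pids) <= agg <= max(pids)


def test_aggregate_of_all_missing_is_missing():
    assert aggregate_pair_pid([("-", "-")]) is None


@pytest.mark.parametrize("length,threshold,expected", [
    (33852, 0.995, 170),   # the 40-marker panel's total nucleotide length
    (200, 0.995, 1),
    (1000, 0.99, 10),
])
def test_min_varied_positions(length, threshold, expected):
    assert min_varied_positions(length, threshold) == expected


def test_min_varied_positions_definition_holds():
    for L, t in [(33852, 0.995), (200, 0.995), (997, 0.97)]:
        d = min_varied_positions(L, t)
        assert (L - d) / L <= t + 1e-12
        assert (L - (d - 1)) / L > t - 1e-12
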