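"""Profile construction, local search, E-values and two-pass copy detection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_force_local_profile_score
from uscg._alphabet import AA, BACKGROUND, X_INDEX, encode
from uscg.detect import (DEFAULT_K, DEFAULT_LAMBDA, SCORE_FLOOR, Proteome,
                         build_profile, detect_copies, estimate_evalue,
                         score_threshold_for_evalue, search_profile)
from uscg.synthetic_data import CommunitySpec, generate_community


# ---------------------------------------------------------------------------
# build_profile
# ---------------------------------------------------------------------------

def test_single_row_profile_at_vanishing_pseudocount():
    """alpha -> 0: the observed residue scores log2(1/bg), others hit the floor."""
    prof = build_profile(["ACD"], "COG0001", pseudocount_weight=1e-12)
    for col, res in enumerate("ACD"):
        i = AA.index(res)
        assert prof.scores[col, i] == pytest.approx(np.log2(1 / BACKGROUND[i]), rel=1e-6)
        others = np.delete(prof.scores[col, :X_INDEX], i)
        assert (others == SCORE_FLOOR).all()


def test_background_frequency_column_scores_zero():
    """A column observing every residue at its background frequency scores 0."""
    # one-column MSA whose row frequencies approximate the background
    counts = np.round(BACKGROUND * 100000).astype(int)
    rows = [a for a, c in zip(AA, counts) for _ in range(c)]
    prof = build_profile(rows, "COG0001", pseudocount_weight=1.0)
    assert np.allclose(prof.scores[0, :X_INDEX], 0.0, atol=5e-3)


def test_three_row_profile_matches_hand_computed_formula():
    """alpha = 1, uniform background: scores follow log2((f + bg)/(2 bg))."""
    msa = ["AC", "AD", "AC"]
    bg = np.full(20, 1 / 20)
    prof = build_profile(msa, "COG0001", pseudocount_weight=1.0, background=bg)
    # column 0: f(A) = 1 -> log2((1 + 0.05)/0.1); absent residues: log2(0.05/0.1) = -1
    assert prof.scores[0, AA.index("A")] == pytest.approx(math.log2(1.05 / 0.1))
    assert prof.scores[0, AA.index("C")] == pytest.approx(-1.0)
    # column 1: f(C) = 2/3, f(D) = 1/3
    assert prof.scores[1, AA.index("C")] == pytest.approx(math.log2((2 / 3 + 0.05) / 0.1))
    assert prof.scores[1, AA.index("D")] == pytest.approx(math.log2((1 / 3 + 0.05) / 0.1))
    assert prof.scores[1, AA.index("A")] == pytest.approx(-1.0)


def test_majority_gap_columns_dropped():
    msa = ["A-C", "A-C", "AGC", "A-C"]
    prof = build_profile(msa, "COG0001")
    assert prof.length == 2


def test_profile_rejects_bad_alignments():
    with pytest.raises(ValueError):
        build_profile([], "COG0001")
    with pytest.raises(ValueError):
        build_profile(["AC", "A"], "COG0001")


def test_x_column_scores_zero():
    prof = build_profile(["ACD"], "COG0001")
    assert (prof.scores[:, X_INDEX] == 0).all()


# ---------------------------------------------------------------------------
# search_profile
# ---------------------------------------------------------------------------

def test_self_search_recovers_full_span_and_self_score():
    seq = "MKWVTFISLLFLFSSAYS"
    prof = build_profile([seq], "COG0001", pseudocount_weight=0.5)
    hit = search_profile(prof, seq)
    assert hit.aligned_span == (0, len(seq))
    assert hit.profile_span == (0, prof.length)
    expected = sum(prof.scores[i, encode(seq)[i]] for i in range(len(seq)))
    assert hit.score == pytest.approx(expected)


def test_all_negative_profile_gives_empty_alignment():
    prof = build_profile(["WWWWW"], "COG0001", pseudocount_weight=1e-12)
    hit = search_profile(prof, "AAAAA")   # A vs W-only columns: floor everywhere
    assert hit.score == 0.0
    assert hit.aligned_span == (0, 0)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(data=st.data())
def test_local_search_agrees_with_brute_force(data):
    """DP optimum equals exhaustive enumeration for profiles <=5 x proteins <=8."""
    rng_seed = data.draw(st.integers(0, 10_000))
    rng = np.random.default_rng(rng_seed)
    rows = ["".join(rng.choice(list(AA), size=rng.integers(2, 6)))
            for _ in range(3)]
    rows = [r.ljust(len(max(rows, key=len)), rows[0][0]) for r in rows]
    prof = build_profile(rows, "COG0001", pseudocount_weight=0.7)
    protein = "".join(rng.choice(list(AA), size=rng.integers(3, 9)))
    hit = search_profile(prof, protein, 5.0, 1.0)
    assert hit.score == pytest.approx(
        brute_force_local_profile_score(prof.scores, protein, 5.0, 1.0))


def test_appending_matching_column_never_decreases_score():
    rng = np.random.default_rng(2)
    base = "".join(rng.choice(list(AA), size=12))
    prof_small = build_profile([base], "COG0001", pseudocount_weight=0.5)
    prof_big = build_profile([base + "W"], "COG0001", pseudocount_weight=0.5)
    protein = base + "W"
    assert (search_profile(prof_big, protein).score
            >= search_profile(prof_small, protein).score)


# ---------------------------------------------------------------------------
# E-values
# ---------------------------------------------------------------------------

def test_evalue_closed_form_substitutions():
    assert estimate_evalue(0.0, 100, 10_000) == pytest.approx(
        DEFAULT_K * 100 * 10_000)
    # monotone decrease toward 0 with score
    scores = np.linspace(0, 500, 40)
    evals = [estimate_evalue(s, 100, 10_000) for s in scores]
    assert all(a > b for a, b in zip(evals, evals[1:]))
    assert evals[-1] < 1e-40


def test_evalue_threshold_inversion():
    """Inverting the closed form reproduces the 1e-15 cutoff score."""
    s_star = score_threshold_for_evalue(1e-15, 100, 10_000)
    assert estimate_evalue(s_star, 100, 10_000) == pytest.approx(1e-15, rel=1e-9)
    assert estimate_evalue(s_star + 1, 100, 10_000) < 1e-15


def test_evalue_monotone_in_database_size():
    assert estimate_evalue(50, 100, 20_000) > estimate_evalue(50, 100, 10_000)


def test_evalue_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        estimate_evalue(10, 0, 100)
    with pytest.raises(ValueError):
        estimate_evalue(10, 100, 100, lam=-1)


# ---------------------------------------------------------------------------
# detect_copies on planted truth
# ---------------------------------------------------------------------------

def test_detection_recovers_planted_copy_numbers(default_community, default_detection):
    hits, matrix = default_detection
    truth = default_community.truth.copy_number
    got = matrix.counts.loc[truth.index, truth.columns].to_numpy()
    assert (got == truth.to_numpy()).mean() >= 0.99
    assert all(h.source == "primary" for h in hits)


def test_detection_handles_duplication_and_loss():
    com = generate_community(CommunitySpec(
        seed=3, n_genera=2, species_per_genus=2, strains_per_species=2,
        n_markers=10, dup_rate=0.15, loss_rate=0.15))
    from uscg.detect import build_profile
    profiles = [build_profile(rows, cog) for cog, rows in sorted(com.seed_msas.items())]
    _, matrix = detect_copies(com.proteomes, profiles)
    truth = com.truth.copy_number
    assert truth.to_numpy().min() == 0 and truth.to_numpy().max() == 2
    got = matrix.counts.loc[truth.index, truth.columns]
    assert (got.to_numpy() == truth.to_numpy()).all()


def test_union_counts_dominate_primary_counts(default_detection):
    _, matrix = default_detection
    assert (matrix.counts.to_numpy() >= matrix.source_counts.to_numpy()).all()


def test_one_protein_assigned_to_at_most_one_cog(default_detection):
    hits, _ = default_detection
    seen = {}
    for h in hits:
        key = (h.genome_id, h.protein_id)
        assert key not in seen or seen[key] == h.cog_id
        seen[key] = h.cog_id
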