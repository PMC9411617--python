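"""Independent brute-force alignment oracles for cross-checking the dynamic programs.

These enumerate every gapped alignment explicitly and score it
path-independently (match columns by the scoring matrix; each maximal gap
run costs open + len*extend). They are deliberately exponential and only
usable on tiny instances.
"""

from __future__ import annotations

import functools

import numpy as np

from uscg._alphabet import BLOSUM62, encode


def _score_alignment(cols: list[tuple[int, int]], score_at, gap_open: float,
                     gap_extend: float) -> float:
    """Path-independent score of an alignment given as (row_idx, col_idx) columns.

    An index of -1 denotes a gap; row_idx indexes the first sequence (or the
    profile), col_idx the second sequence.
    """
    total = 0.0
    in_gap_a = in_gap_b = False
    for ia, ib in cols:
        if ia == -1:
            total -= gap_extend + (0.0 if in_gap_a else gap_open)
            in_gap_a, in_gap_b = True, False
        elif ib == -1:
            total -= gap_extend + (0.0 if in_gap_b else gap_open)
            in_gap_a, in_gap_b = False, True
        else:
            total += score_at(ia, ib)
            in_gap_a = in_gap_b = False
    return total


def _enumerate_alignments(n: int, m: int):
    """Yield every global alignment of ranges (0..n) x (0..m) as column lists."""

    @functools.lru_cache(maxsize=None)
    def rec(i: int, j: int) -> list[tuple[tuple[int, int], ...]]:
        if i == n and j == m:
            return [()]
        out = []
        if i < n and j < m:
            out += [((i, j),) + rest for rest in rec(i + 1, j + 1)]
        if i < n:
            out += [((i, -1),) + rest for rest in rec(i + 1, j)]
        if j < m:
            out += [((-1, j),) + rest for rest in rec(i, j + 1)]
        return out

    yield from rec(0, 0)


def brute_force_global_score(a: str, b: str, gap_open: float = 11.0,
                             gap_extend: float = 1.0) -> float:
    """Maximum global affine-gap BLOSUM62 score by exhaustive enumeration."""
    ea, eb = encode(a), encode(b)

    def score_at(i: int, j: int) -> float:
        return float(BLOSUM62[ea[i], eb[j]])

    return max(_score_alignment(list(cols), score_at, gap_open, gap_extend)
               for cols in _enumerate_alignments(len(a), len(b)))


def brute_force_local_profile_score(profile_scores: np.ndarray, protein: str,
                                    gap_open: float = 11.0,
                                    gap_extend: float = 1.0) -> float:
    """Best local profile-vs-sequence score over all subranges and alignments."""
    ep = encode(protein)
    L, m = profile_scores.shape[0], len(protein)

    def score_at_offset(pi0: int, pj0: int):
        def score_at(i: int, j: int) -> float:
            return float(profile_scores[pi0 + i, ep[pj0 + j]])
        return score_at

    best = 0.0
    for i0 in range(L):
        for i1 in range(i0 + 1, L + 1):
            for j0 in range(m):
                for j1 in range(j0 + 1, m + 1):
                    score_at = score_at_offset(i0, j0)
                    for cols in _enumerate_alignments(i1 - i0, j1 - j0):
                        s = _score_alignment(list(cols), score_at, gap_open, gap_extend)
                        if s > best:
                            best = s
    return best
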