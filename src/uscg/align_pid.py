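"""Pairwise protein alignment and the percent-identity (PID) statistic.

PID between two marker copies is defined on a gapped pairwise alignment
after removing columns gapped in *both* sequences: it is 100 x matches /
(matches + mismatches + indel positions). Indel positions stay in the
denominator — only indel-versus-indel columns are removed. The pairwise
aligner is Needleman–Wunsch with affine gaps under BLOSUM62 (gap open 11,
extend 1: a gap of length k costs open + k*extend) and a deterministic
traceback preferring diagonal over up (gap in the second sequence) over
left. A pair can alternatively be projected out of a multiple alignment,
mirroring per-marker MSA workflows.

The aggregate PID of a genome pair over many markers defaults to the
concatenated-column definition, 100 x (sum of matches)/(sum of aligned
positions), i.e. the aligned-length-weighted mean of per-marker PIDs; an
unweighted mean mode is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from ._alphabet import BLOSUM62, encode

GAP_CHARS = frozenset("-.")

_DIAG, _UP, _LEFT = 0, 1, 2
_NEG = -1e30


@njit(cache=True)
def _nw_affine(a, b, S, gap_open, gap_extend):  # pragma: no cover - exercised via global_align
    n, m = a.shape[0], b.shape[0]
    M = np.full((n + 1, m + 1), _NEG)
    Ix = np.full((n + 1, m + 1), _NEG)   # gap in b: consumes a ("up")
    Iy = np.full((n + 1, m + 1), _NEG)   # gap in a: consumes b ("left")
    pM = np.zeros((n + 1, m + 1), dtype=np.int8)
    pX = np.zeros((n + 1, m + 1), dtype=np.int8)
    pY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -gap_open - i * gap_extend
        pX[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Iy[0, j] = -gap_open - j * gap_extend
        pY[0, j] = 0 if j == 1 else 2
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = S[ai, b[j - 1]]
            # diagonal state: tie-break M > Ix > Iy
            best = M[i - 1, j - 1]
            p = 0
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
                p = 1
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
                p = 2
            M[i, j] = best + s
            pM[i, j] = p
            # gap in b (up)
            best = M[i - 1, j] - gap_open - gap_extend
            p = 0
            if Ix[i - 1, j] - gap_extend > best:
                best = Ix[i - 1, j] - gap_extend
                p = 1
            if Iy[i - 1, j] - gap_open - gap_extend > best:
                best = Iy[i - 1, j] - gap_open - gap_extend
                p = 2
            Ix[i, j] = best
            pX[i, j] = p
            # gap in a (left)
            best = M[i, j - 1] - gap_open - gap_extend
            p = 0
            if Ix[i, j - 1] - gap_open - gap_extend > best:
                best = Ix[i, j - 1] - gap_open - gap_extend
                p = 1
            if Iy[i, j - 1] - gap_extend > best:
                best = Iy[i, j - 1] - gap_extend
                p = 2
            Iy[i, j] = best
            pY[i, j] = p
    # final state: tie-break M > Ix > Iy
    state = 0
    score = M[n, m]
    if Ix[n, m] > score:
        score = Ix[n, m]
        state = 1
    if Iy[n, m] > score:
        score = Iy[n, m]
        state = 2
    # traceback
    ops = np.empty(n + m, dtype=np.int8)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            ops[k] = _DIAG
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            ops[k] = _UP
            state = pX[i, j]
            i -= 1
        else:
            ops[k] = _LEFT
            state = pY[i, j]
            j -= 1
        k += 1
    return score, ops[:k][::-1].copy()


@dataclass(frozen=True)
class PidStats:
    """Identity statistics of one both-gap-free aligned pair."""

    matches: int
    mismatches: int
    indel_positions: int

    @property
    def aligned_length(self) -> int:
        return self.matches + self.mismatches + self.indel_positions

    @property
    def pid_pct(self) -> float:
        return 100.0 * self.matches / self.aligned_length


@dataclass(frozen=True)
class AlignmentResult:
    """A scored global pairwise alignment with its identity statistics."""

    aligned_a: str
    aligned_b: str
    score: float
    matches: int
    mismatches: int
    indel_positions: int

    @property
    def pid_pct(self) -> float:
        return 100.0 * self.matches / (self.matches + self.mismatches + self.indel_positions)


def global_align(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0,
                 matrix: np.ndarray = BLOSUM62) -> AlignmentResult:
    """Global Needleman–Wunsch alignment of two protein sequences.

    Affine gap cost ``open + k*extend`` for a gap of length ``k``; BLOSUM62
    scoring with X scoring 0 against everything; deterministic traceback
    (diagonal > up > left on ties).
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if gap_open <= 0 or gap_extend <= 0:
        raise ValueError("gap penalties must be positive")
    score, ops = _nw_affine(encode(a), encode(b), matrix, float(gap_open), float(gap_extend))
    ai = bi = 0
    row_a: list[str] = []
    row_b: list[str] = []
    for op in ops:
        if op == _DIAG:
            row_a.append(a[ai]); ai += 1
            row_b.append(b[bi]); bi += 1
        elif op == _UP:
            row_a.append(a[ai]); ai += 1
            row_b.append("-")
        else:
            row_a.append("-")
            row_b.append(b[bi]); bi += 1
    stats = compute_pid("".join(row_a), "".join(row_b))
    assert stats is not None
    return AlignmentResult("".join(row_a), "".join(row_b), float(score),
                           stats.matches, stats.mismatches, stats.indel_positions)


def project_pair_from_msa(msa: Sequence[str], i: int, j: int) -> tuple[str, str]:
    """Extract rows ``i`` and ``j`` of an MSA, deleting every both-gap column."""
    ri, rj = msa[i], msa[j]
    if len(ri) != len(rj):
        raise ValueError("MSA rows have unequal lengths")
    keep_a: list[str] = []
    keep_b: list[str] = []
    for ca, cb in zip(ri, rj):
        if ca in GAP_CHARS and cb in GAP_CHARS:
            continue
        keep_a.append(ca)
        keep_b.append(cb)
    return "".join(keep_a), "".join(keep_b)


def compute_pid(aligned_a: str, aligned_b: str) -> PidStats | None:
    """Identity statistics of an aligned pair (both-gap columns ignored).

    Residue comparison is case-insensitive and ``X`` matches ``X``. Returns
    ``None`` for a zero-length alignment (undefined PID, a missing datum).
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences have unequal lengths")
    matches = mismatches = indels = 0
    for ca, cb in zip(aligned_a.upper(), aligned_b.upper()):
        ga, gb = ca in GAP_CHARS, cb in GAP_CHARS
        if ga and gb:
            continue
        if ga or gb:
            indels += 1
        elif ca == cb:
            matches += 1
        else:
            mismatches += 1
    if matches + mismatches + indels == 0:
        return None
    return PidStats(matches, mismatches, indels)


def aggregate_pair_pid(aligned_pairs: Iterable[tuple[str, str]],
                       mode: str = "concat") -> float | None:
    """Aggregate PID of one genome pair over several per-marker aligned pairs.

    ``concat`` (default) pools columns across markers: 100 x total matches /
    total aligned positions. ``mean`` averages per-marker PIDs unweighted.
    Markers with zero aligned length are skipped; returns ``None`` if none
    remain.
    """
    if mode not in ("concat", "mean"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    stats = [s for s in (compute_pid(a, b) for a, b in aligned_pairs) if s is not None]
    if not stats:
        return None
    if mode == "mean":
        return float(np.mean([s.pid_pct for s in stats]))
    total = sum(s.aligned_length for s in stats)
    return 100.0 * sum(s.matches for s in stats) / total


def min_varied_positions(total_length: int, pid_threshold: float) -> int:
    """Smallest number of varied positions putting a pair at or below a PID threshold.

    The smallest integer ``d`` with ``(total_length - d)/total_length <=
    pid_threshold`` (threshold as a fraction), i.e. the variation needed
    before two genomes become distinguishable at that threshold.
    """
    if not 0 < pid_threshold < 1:
        raise ValueError("pid_threshold must be a fraction in (0, 1)")
    if total_length < 1:
        raise ValueError("total_length must be positive")
    # d = L - floor(L*t); epsilon guards float representation of thresholds like 0.995
    return total_length - math.floor(total_length * pid_threshold + 1e-9)
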