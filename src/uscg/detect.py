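"""Marker detection: PSSM construction, local profile search, two-pass assignment.

Copies of each marker gene are found in a genome's protein complement with a
single position-specific scoring model per COG, run in two tiers that mirror
the common extract-then-rescue design of marker pipelines:

* **primary** pass — candidate proteins (shortlisted by exact k-mer seeding
  against the profile consensus, BLAST-style) are aligned to the profile by
  a Smith–Waterman local dynamic program with affine gaps; hits must reach
  the E-value cutoff (default 1e-15) *and* cover a minimum fraction of the
  profile's match columns;
* **rescue** pass — only for genome x marker cells left empty by the primary
  pass: every protein is re-searched exhaustively (no seeding) with the same
  E-value cutoff but no coverage floor.

A protein is assigned to at most one COG — lowest E-value wins, ties broken
by lexicographic COG id — so one ribosomal protein can never inflate several
markers' counts. E-values use the ungapped Karlin–Altschul form
``E = K*m*n*exp(-lambda*S)`` with the conventional BLOSUM62-scale constants
(lambda 0.267, K 0.041); with the enormous score gap between genuine marker
copies and background matches, the E-value serves as a threshold scale, not
a calibrated significance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from numba import njit

from ._alphabet import ALPHABET, BACKGROUND, N_SYMBOLS, X_INDEX, encode
from .io import logger
from .occurrence import OccurrenceMatrix

DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041
SCORE_FLOOR = -8.0
DEFAULT_E_CUTOFF = 1e-15


@dataclass(frozen=True)
class Proteome:
    """One genome's protein complement: unique protein ids to sequences."""

    genome_id: str
    proteins: dict[str, str]

    def __post_init__(self) -> None:
        for pid, seq in self.proteins.items():
            if not seq:
                raise ValueError(f"{self.genome_id}/{pid}: empty protein sequence")

    @property
    def n_residues(self) -> int:
        return sum(len(s) for s in self.proteins.values())


@dataclass(frozen=True)
class Profile:
    """Position-specific log-odds scoring model for one marker family.

    ``scores`` is a (length x 21) array in bits: score(r) =
    log2((f_r + alpha*bg_r) / ((1 + alpha)*bg_r)) per match column, floored
    at -8; the X column is 0 everywhere. Match columns are alignment columns
    with gap fraction <= 50%.
    """

    cog_id: str
    length: int
    scores: np.ndarray
    background: np.ndarray
    pseudocount_weight: float
    consensus: str

    def self_score(self) -> float:
        """Sum of the per-column maxima (score of the consensus sequence)."""
        return float(self.scores[:, :X_INDEX].max(axis=1).sum())


@dataclass(frozen=True)
class Hit:
    """One accepted profile-to-protein match."""

    genome_id: str
    protein_id: str
    cog_id: str
    raw_score: float
    bit_score: float
    e_value: float
    source: str                      # "primary" | "rescue"
    aligned_span: tuple[int, int]    # half-open, 0-based, on the protein
    profile_span: tuple[int, int]    # half-open, 0-based, on the profile


def build_profile(msa: Sequence[str], cog_id: str = "",
                  pseudocount_weight: float = 1.0,
                  background: np.ndarray = BACKGROUND) -> Profile:
    """Build a PSSM from an aligned family of sequences.

    Columns with more than 50% gaps are dropped from the match states.
    Observed frequencies are computed over non-gap, non-X residues and mixed
    with the background via the pseudocount weight ``alpha``.
    """
    if not msa:
        raise ValueError("empty alignment")
    width = len(msa[0])
    if any(len(row) != width for row in msa):
        raise ValueError("ragged alignment rows")
    if width == 0:
        raise ValueError("zero-width alignment")
    if pseudocount_weight < 0:
        raise ValueError("pseudocount weight must be non-negative")
    alpha = float(pseudocount_weight)
    bg = np.asarray(background, dtype=float)
    bg = bg / bg.sum()

    gap_mask = np.array([[c in "-." for c in row] for row in msa], dtype=bool)
    enc = np.stack([encode(row.replace("-", "X").replace(".", "X")) for row in msa])

    keep = gap_mask.mean(axis=0) <= 0.5
    if not keep.any():
        raise ValueError(f"profile {cog_id or '?'}: no match columns after gap filtering")

    cols = np.flatnonzero(keep)
    scores = np.zeros((len(cols), N_SYMBOLS), dtype=np.float64)
    consensus: list[str] = []
    for out_i, col in enumerate(cols):
        residues = enc[~gap_mask[:, col], col]
        residues = residues[residues != X_INDEX]
        counts = np.bincount(residues, minlength=N_SYMBOLS)[:X_INDEX].astype(float)
        total = counts.sum()
        freqs = counts / total if total > 0 else np.zeros_like(counts)
        with np.errstate(divide="ignore"):
            col_scores = np.log2((freqs + alpha * bg) / ((1.0 + alpha) * bg))
        scores[out_i, :X_INDEX] = np.maximum(col_scores, SCORE_FLOOR)
        consensus.append(ALPHABET[int(np.argmax(scores[out_i, :X_INDEX]))])
    return Profile(cog_id, len(cols), scores, bg, alpha, "".join(consensus))


# ---------------------------------------------------------------------------
# Local profile-to-sequence alignment
# ---------------------------------------------------------------------------

_NEG = -1e30


@njit(cache=True)
def _sw_profile(P, b, gap_open, gap_extend):  # pragma: no cover - exercised via search_profile
    """Affine-gap Smith–Waterman of a profile (rows) against a sequence (cols).

    Returns (score, prot_start, prot_end, prof_start, prof_end); empty span
    when the best score is 0. Tie-breaks: diagonal > gap-in-protein
    (consumes a profile column) > gap-in-profile; a new local alignment is
    started only when continuing would score < 0; best cell = first
    strictly-better cell in row-major order.
    """
    n, m = P.shape[0], b.shape[0]
    M = np.full((n + 1, m + 1), _NEG)
    Ix = np.full((n + 1, m + 1), _NEG)   # gap in protein (consumes profile row)
    Iy = np.full((n + 1, m + 1), _NEG)   # gap in profile (consumes protein residue)
    # pointers: 0=M, 1=Ix, 2=Iy, 3=local start
    pM = np.full((n + 1, m + 1), 3, dtype=np.int8)
    pX = np.zeros((n + 1, m + 1), dtype=np.int8)
    pY = np.zeros((n + 1, m + 1), dtype=np.int8)
    best_score = 0.0
    bi = bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = P[i - 1, b[j - 1]]
            prev = M[i - 1, j - 1]
            p = 0
            if Ix[i - 1, j - 1] > prev:
                prev = Ix[i - 1, j - 1]
                p = 1
            if Iy[i - 1, j - 1] > prev:
                prev = Iy[i - 1, j - 1]
                p = 2
            if prev <= 0.0:
                prev = 0.0
                p = 3
            M[i, j] = prev + s
            pM[i, j] = p

            val = M[i - 1, j] - gap_open - gap_extend
            p = 0
            if Ix[i - 1, j] - gap_extend > val:
                val = Ix[i - 1, j] - gap_extend
                p = 1
            Ix[i, j] = val
            pX[i, j] = p

            val = M[i, j - 1] - gap_open - gap_extend
            p = 0
            if Iy[i, j - 1] - gap_extend > val:
                val = Iy[i, j - 1] - gap_extend
                p = 2
            Iy[i, j] = val
            pY[i, j] = p

            if M[i, j] > best_score:
                best_score = M[i, j]
                bi, bj = i, j
    if best_score <= 0.0:
        return 0.0, 0, 0, 0, 0
    # traceback from (bi, bj) in state M
    i, j = bi, bj
    state = 0
    while True:
        if state == 0:
            nxt = pM[i, j]
            i -= 1
            j -= 1
            if nxt == 3:
                break
            state = nxt
        elif state == 1:
            state = pX[i, j]
            i -= 1
        else:
            state = pY[i, j]
            j -= 1
    return best_score, j, bj, i, bi


@dataclass(frozen=True)
class ProfileHit:
    """Raw output of one local profile search (pre E-value filtering)."""

    score: float
    aligned_span: tuple[int, int]   # on the protein
    profile_span: tuple[int, int]   # on the profile

    @property
    def profile_coverage_len(self) -> int:
        return self.profile_span[1] - self.profile_span[0]


def search_profile(profile: Profile, protein: str,
                   gap_open: float = 11.0, gap_extend: float = 1.0) -> ProfileHit:
    """Best local alignment of a profile against one protein sequence.

    Smith–Waterman over profile columns x protein positions with affine
    gaps; the score is floored at 0 (empty alignment allowed).
    """
    if gap_open <= 0 or gap_extend <= 0:
        raise ValueError("gap penalties must be positive")
    if not protein:
        raise ValueError("empty protein sequence")
    score, ps, pe, fs, fe = _sw_profile(profile.scores, encode(protein),
                                        float(gap_open), float(gap_extend))
    return ProfileHit(float(score), (int(ps), int(pe)), (int(fs), int(fe)))


def estimate_evalue(raw_score: float, profile_length: int, db_residues: int,
                    lam: float = DEFAULT_LAMBDA, K: float = DEFAULT_K) -> float:
    """Ungapped Karlin–Altschul E-value: ``E = K*m*n*exp(-lambda*S)``."""
    if profile_length <= 0 or db_residues <= 0:
        raise ValueError("profile_length and db_residues must be positive")
    if lam <= 0 or K <= 0:
        raise ValueError("lambda and K must be positive")
    return K * profile_length * db_residues * math.exp(-lam * raw_score)


def bit_score(raw_score: float, lam: float = DEFAULT_LAMBDA, K: float = DEFAULT_K) -> float:
    """Normalised bit score ``(lambda*S - ln K) / ln 2``."""
    return (lam * raw_score - math.log(K)) / math.log(2.0)


def score_threshold_for_evalue(e_value: float, profile_length: int, db_residues: int,
                               lam: float = DEFAULT_LAMBDA, K: float = DEFAULT_K) -> float:
    """Raw score at which the E-value equals ``e_value`` (inverse of the closed form)."""
    return math.log(K * profile_length * db_residues / e_value) / lam


# ---------------------------------------------------------------------------
# Two-pass copy detection
# ---------------------------------------------------------------------------

def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def detect_copies(proteomes: Iterable[Proteome], profiles: Sequence[Profile],
                  e_cutoff: float = DEFAULT_E_CUTOFF,
                  gap_open: float = 11.0, gap_extend: float = 1.0,
                  min_coverage_primary: float = 0.7,
                  min_coverage_rescue: float = 0.0,
                  seed_kmer: int = 4, min_seed_kmers: int = 8,
                  ) -> tuple[list[Hit], OccurrenceMatrix]:
    """Detect marker copies in each proteome and tabulate copy numbers.

    The primary pass searches only proteins sharing at least
    ``min_seed_kmers`` exact ``seed_kmer``-mers with the profile consensus
    and requires profile coverage >= ``min_coverage_primary``; the rescue
    pass runs exhaustively, but only for genome x marker cells with no
    primary hit, with coverage floor ``min_coverage_rescue``. Both passes
    use the same E-value cutoff. Proteins already assigned by the primary
    pass are never reassigned by rescue, so union counts dominate
    primary-only counts cell-wise.
    """
    if e_cutoff <= 0:
        raise ValueError("e_cutoff must be positive")
    profiles = sorted(profiles, key=lambda p: p.cog_id)
    cog_ids = [p.cog_id for p in profiles]
    profile_kmers = {p.cog_id: _kmer_set(p.consensus, seed_kmer) for p in profiles}

    all_hits: list[Hit] = []
    genome_ids: list[str] = []
    counts_rows: list[list[int]] = []
    primary_rows: list[list[int]] = []

    for prot in proteomes:
        genome_ids.append(prot.genome_id)
        db_n = prot.n_residues
        pids = sorted(prot.proteins)
        pkmers = {pid: _kmer_set(prot.proteins[pid], seed_kmer) for pid in pids}

        def _search(profile: Profile, pid: str, source: str) -> Hit | None:
            ph = search_profile(profile, prot.proteins[pid], gap_open, gap_extend)
            if ph.score <= 0:
                return None
            cov_floor = min_coverage_primary if source == "primary" else min_coverage_rescue
            if ph.profile_coverage_len < cov_floor * profile.length:
                return None
            e = estimate_evalue(ph.score, profile.length, db_n)
            if e > e_cutoff:
                return None
            return Hit(prot.genome_id, pid, profile.cog_id, ph.score,
                       bit_score(ph.score), e, source, ph.aligned_span, ph.profile_span)

        # pass 1: seeded strict search
        primary_hits: list[Hit] = []
        for profile in profiles:
            cons_kmers = profile_kmers[profile.cog_id]
            for pid in pids:
                if len(pkmers[pid] & cons_kmers) < min_seed_kmers:
                    continue
                hit = _search(profile, pid, "primary")
                if hit is not None:
                    primary_hits.append(hit)

        # one-COG-per-protein assignment: lowest E, then lexicographic COG id
        assigned = _assign_best(primary_hits)
        primary_count = {c: 0 for c in cog_ids}
        for hit in assigned.values():
            primary_count[hit.cog_id] += 1

        # pass 2: exhaustive rescue for empty cells, unassigned proteins only
        rescue_hits: list[Hit] = []
        for profile in profiles:
            if primary_count[profile.cog_id] > 0:
                continue
            for pid in pids:
                if pid in assigned:
                    continue
                hit = _search(profile, pid, "rescue")
                if hit is not None:
                    rescue_hits.append(hit)
        rescued = _assign_best(rescue_hits)

        final = dict(assigned)
        final.update(rescued)
        total_count = {c: 0 for c in cog_ids}
        for hit in final.values():
            total_count[hit.cog_id] += 1

        all_hits.extend(final[pid] for pid in sorted(final))
        counts_rows.append([total_count[c] for c in cog_ids])
        primary_rows.append([primary_count[c] for c in cog_ids])

    matrix = OccurrenceMatrix.from_arrays(genome_ids, cog_ids,
                                          np.array(counts_rows, dtype=int),
                                          np.array(primary_rows, dtype=int))
    return all_hits, matrix


def _assign_best(hits: list[Hit]) -> dict[str, Hit]:
    """Per-protein best hit: lowest E-value, ties by lexicographic COG id."""
    best: dict[str, Hit] = {}
    for hit in sorted(hits, key=lambda h: (h.protein_id, h.e_value, h.cog_id)):
        best.setdefault(hit.protein_id, hit)
    return best


def collect_marker_sequences(hits: Iterable[Hit], proteomes: Iterable[Proteome],
                             ) -> dict[tuple[str, str], list[str]]:
    """Group detected copy sequences by (genome_id, cog_id), full-length proteins."""
    seqs = {p.genome_id: p.proteins for p in proteomes}
    out: dict[tuple[str, str], list[str]] = {}
    for hit in hits:
        out.setdefault((hit.genome_id, hit.cog_id), []).append(
            seqs[hit.genome_id][hit.protein_id])
    return out


def hits_to_frame(hits: Sequence[Hit]):
    """Hits as a TSV-ready DataFrame (spans 0-based, half-open)."""
    import pandas as pd

    return pd.DataFrame(
        [(h.genome_id, h.protein_id, h.cog_id, h.raw_score, h.bit_score,
          h.e_value, h.source, h.aligned_span[0], h.aligned_span[1])
         for h in hits],
        columns=["genome_id", "protein_id", "cog_id", "raw_score", "bit_score",
                 "e_value", "source", "span_start", "span_end"])
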