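"""Species-pair and strain-pair percent-identity distributions and separability.

Species pairs are unordered genome pairs from the same genus but different
species; strain pairs are genome pairs within one species. For each pair
the per-marker copies are globally aligned and the aggregate PID computed;
the separability report then gives the empirical CDF of aggregate PIDs and
the fraction strictly above a threshold (default 99.5%, the operational
limit beyond which current tools cannot tell two genomes apart).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align_pid import aggregate_pair_pid, compute_pid, global_align
from .io import logger

SPECIES_PAIR = "species_pair"
STRAIN_PAIR = "strain_pair"


@dataclass(frozen=True)
class TaxonomyRecord:
    """Taxonomic assignment of one genome."""

    genome_id: str
    genus: str
    species: str
    strain: str = ""

    def __post_init__(self) -> None:
        if not self.genome_id or not self.genus or not self.species:
            raise ValueError("genome_id, genus and species must be non-empty")


def taxonomy_from_frame(df: pd.DataFrame) -> list[TaxonomyRecord]:
    return [TaxonomyRecord(r.genome_id, r.genus, r.species, getattr(r, "strain", "") or "")
            for r in df.itertuples(index=False)]


@dataclass(frozen=True)
class PairPID:
    """Aggregate and per-marker PIDs for one genome pair."""

    id_a: str
    id_b: str
    level: str
    per_marker: dict[str, dict[str, float]]
    aggregate_pid_pct: float | None
    n_markers_used: int


@dataclass
class SeparabilityReport:
    """PID distribution summary for one pair level."""

    level: str
    n_pairs: int
    mean_pid: float
    median_pid: float
    fraction_above_threshold: float
    threshold_pct: float
    cdf_points: list[tuple[float, float]]

    def cdf_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cdf_points, columns=["pid_pct", "cumulative_fraction"])


def enumerate_taxon_pairs(taxonomy: Sequence[TaxonomyRecord], level: str,
                          mode: str = "all") -> list[tuple[str, str]]:
    """Enumerate genome pairs at a taxonomic level, deterministically ordered.

    ``species_pair``: same genus, different species; ``strain_pair``: same
    species, different genome. Groups with fewer than two eligible members
    contribute nothing. ``mode="all"`` uses every cross-group genome pair;
    ``mode="representative"`` keeps only the lexicographically first genome
    of each species before pairing (species level only).
    """
    if mode not in ("all", "representative"):
        raise ValueError(f"unknown pair mode {mode!r}")
    pairs: list[tuple[str, str]] = []
    if level == SPECIES_PAIR:
        by_genus: dict[str, list[TaxonomyRecord]] = {}
        for rec in taxonomy:
            by_genus.setdefault(rec.genus, []).append(rec)
        for genus in sorted(by_genus):
            recs = by_genus[genus]
            if mode == "representative":
                rep: dict[str, str] = {}
                for rec in recs:
                    if rec.species not in rep or rec.genome_id < rep[rec.species]:
                        rep[rec.species] = rec.genome_id
                ids = [(sp, gid) for sp, gid in rep.items()]
                for (sa, ga), (sb, gb) in itertools.combinations(sorted(ids, key=lambda x: x[1]), 2):
                    if sa != sb:
                        pairs.append(tuple(sorted((ga, gb))))
            else:
                for ra, rb in itertools.combinations(sorted(recs, key=lambda r: r.genome_id), 2):
                    if ra.species != rb.species:
                        pairs.append(tuple(sorted((ra.genome_id, rb.genome_id))))
    elif level == STRAIN_PAIR:
        by_species: dict[tuple[str, str], list[str]] = {}
        for rec in taxonomy:
            by_species.setdefault((rec.genus, rec.species), []).append(rec.genome_id)
        for key in sorted(by_species):
            for ga, gb in itertools.combinations(sorted(by_species[key]), 2):
                pairs.append((ga, gb))
    else:
        raise ValueError(f"unknown pair level {level!r}")
    return sorted(set(pairs))


def pair_pid_table(pairs: Sequence[tuple[str, str]],
                   sequences: Mapping[tuple[str, str], Sequence[str]],
                   markers: Sequence[str], level: str,
                   aggregation: str = "concat",
                   gap_open: float = 11.0, gap_extend: float = 1.0,
                   ) -> list[PairPID]:
    """Per-pair PIDs over a marker panel.

    ``sequences`` maps (genome_id, cog_id) to the detected copy sequences.
    Markers missing in either genome are skipped; when a genome carries
    several copies of a marker, the copy pair maximising PID is used (the
    upper bound of the pair's similarity). A pair sharing zero markers gets
    a missing aggregate (None), never silently dropped.
    """
    out: list[PairPID] = []
    for ga, gb in pairs:
        per_marker: dict[str, dict[str, float]] = {}
        aligned_pairs: list[tuple[str, str]] = []
        for cog in markers:
            copies_a = sequences.get((ga, cog), ())
            copies_b = sequences.get((gb, cog), ())
            if not copies_a or not copies_b:
                continue
            best = None
            for sa in copies_a:
                for sb in copies_b:
                    res = global_align(sa, sb, gap_open, gap_extend)
                    if best is None or res.pid_pct > best.pid_pct:
                        best = res
            per_marker[cog] = {
                "pid_pct": best.pid_pct,
                "aligned_len": best.matches + best.mismatches + best.indel_positions,
                "matches": best.matches,
            }
            aligned_pairs.append((best.aligned_a, best.aligned_b))
        aggregate = aggregate_pair_pid(aligned_pairs, aggregation) if aligned_pairs else None
        if aggregate is None:
            logger.warning("pair (%s, %s) shares no markers; aggregate PID missing", ga, gb)
        out.append(PairPID(ga, gb, level, per_marker, aggregate, len(per_marker)))
    return out


def separability(pids: Iterable[float], threshold_pct: float = 99.5,
                 level: str = "") -> SeparabilityReport:
    """Empirical CDF of aggregate PIDs and the strictly-above-threshold fraction."""
    values = np.sort(np.asarray([p for p in pids if p is not None], dtype=float))
    if values.size == 0:
        raise ValueError("no PID values to summarise")
    uniq, counts = np.unique(values, return_counts=True)
    cum = np.cumsum(counts) / values.size
    return SeparabilityReport(
        level=level,
        n_pairs=int(values.size),
        mean_pid=float(values.mean()),
        median_pid=float(np.median(values)),
        fraction_above_threshold=float((values > threshold_pct).mean()),
        threshold_pct=threshold_pct,
        cdf_points=[(float(u), float(c)) for u, c in zip(uniq, cum)],
    )


def pair_table_to_frame(table: Sequence[PairPID]) -> pd.DataFrame:
    """Long-format per-pair, per-marker TSV-ready frame plus aggregates."""
    rows = []
    for p in table:
        for cog, m in sorted(p.per_marker.items()):
            rows.append((p.id_a, p.id_b, p.level, cog, m["pid_pct"],
                         m["matches"], m["aligned_len"]))
    return pd.DataFrame(rows, columns=["id_a", "id_b", "level", "cog_id",
                                       "pid_pct", "matches", "aligned_len"])


def aggregate_frame(table: Sequence[PairPID]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.id_a, p.id_b, p.level, p.aggregate_pid_pct, p.n_markers_used)
         for p in table],
        columns=["id_a", "id_b", "level", "aggregate_pid_pct", "n_markers_used"])
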