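"""Universalism and uniqueness statistics from genome x marker copy counts.

*Universalism* of a marker is the percentage of genomes carrying at least
one copy; *uniqueness* the percentage carrying exactly one. Both default to
all genomes in the denominator; a present-genomes uniqueness denominator
(the Parks-style convention) is available behind a flag. Counts carry two
parallel tables: the union of both detection passes and the primary-only
counts, so the statistics can be reported per detection source.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass
class OccurrenceMatrix:
    """Genome x marker copy-count tables (union and primary-only).

    ``counts`` dominates ``source_counts`` elementwise: the rescue pass can
    only add copies. ``unsearchable`` lists markers with no scoring model;
    they are excluded from summary denominators.
    """

    counts: pd.DataFrame
    source_counts: pd.DataFrame
    unsearchable: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.counts.shape != self.source_counts.shape:
            raise ValueError("counts and source_counts have different shapes")
        if (self.counts.to_numpy() < self.source_counts.to_numpy()).any():
            raise ValueError("union counts must dominate primary-only counts")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative copy counts")

    @classmethod
    def from_arrays(cls, genome_ids: Sequence[str], cog_ids: Sequence[str],
                    counts: np.ndarray, source_counts: np.ndarray | None = None,
                    unsearchable: Iterable[str] = ()) -> "OccurrenceMatrix":
        cdf = pd.DataFrame(counts, index=list(genome_ids), columns=list(cog_ids))
        sdf = cdf.copy() if source_counts is None else pd.DataFrame(
            source_counts, index=list(genome_ids), columns=list(cog_ids))
        return cls(cdf, sdf, frozenset(unsearchable))

    @property
    def genome_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def cog_ids(self) -> list[str]:
        return list(self.counts.columns)

    def table(self, mode: str) -> pd.DataFrame:
        if mode == "union":
            return self.counts
        if mode == "primary":
            return self.source_counts
        raise ValueError(f"unknown source mode {mode!r}")


def marker_universalism_uniqueness(matrix: OccurrenceMatrix, cog_id: str,
                                   mode: str = "union",
                                   uniqueness_denominator: str = "all_genomes",
                                   ) -> dict[str, float]:
    """Universalism and uniqueness percentages for one marker.

    universalism = 100 x |{genomes with >=1 copy}| / |genomes|;
    uniqueness   = 100 x |{genomes with exactly 1 copy}| / denominator,
    where the denominator is all genomes (default) or, with
    ``uniqueness_denominator="present_genomes"``, only genomes carrying the
    marker.
    """
    col = matrix.table(mode)[cog_id]
    n = len(col)
    if n == 0:
        raise ValueError("occurrence matrix has zero genomes")
    present = int((col >= 1).sum())
    single = int((col == 1).sum())
    if uniqueness_denominator == "all_genomes":
        uniq_den = n
    elif uniqueness_denominator == "present_genomes":
        uniq_den = present
    else:
        raise ValueError(f"unknown uniqueness denominator {uniqueness_denominator!r}")
    return {
        "universalism_pct": 100.0 * present / n,
        "uniqueness_pct": 100.0 * single / uniq_den if uniq_den else float("nan"),
    }


@dataclass
class SetSummary:
    """Across-marker summary of one set's universalism/uniqueness percentages."""

    per_marker: dict[str, dict[str, dict[str, float]]]   # mode -> cog -> metrics
    across_markers: pd.DataFrame                         # rows metric x mode

    def to_frame(self) -> pd.DataFrame:
        return self.across_markers.copy()


def set_summary(matrix: OccurrenceMatrix, marker_set,
                modes: Sequence[str] = ("primary", "union"),
                uniqueness_denominator: str = "all_genomes") -> SetSummary:
    """Mean/SD/min/median/max of per-marker percentages over a marker set.

    SD is the population standard deviation; the median of an even count is
    the midpoint. Markers flagged unsearchable are excluded.
    """
    members = sorted(set(marker_set.cog_ids) - set(matrix.unsearchable))
    missing = [c for c in members if c not in matrix.counts.columns]
    if missing:
        raise ValueError(f"markers absent from occurrence matrix: {missing[:5]}")
    per_marker: dict[str, dict[str, dict[str, float]]] = {}
    rows = {}
    for mode in modes:
        per_marker[mode] = {
            c: marker_universalism_uniqueness(matrix, c, mode, uniqueness_denominator)
            for c in members}
        for metric in ("universalism_pct", "uniqueness_pct"):
            vals = np.array([per_marker[mode][c][metric] for c in members])
            rows[(metric, mode)] = {
                "mean": vals.mean(),
                "sd": vals.std(ddof=0),
                "minimum": vals.min(),
                "median": float(np.median(vals)),
                "maximum": vals.max(),
            }
    frame = pd.DataFrame(rows).T
    frame.index.names = ["metric", "mode"]
    return SetSummary(per_marker, frame)


def per_genome_marker_counts(matrix: OccurrenceMatrix, marker_set,
                             mode: str = "union") -> pd.DataFrame:
    """Per-genome counts of present and multi-copy set members.

    Returns a DataFrame indexed by genome with columns ``present`` (members
    with >=1 copy) and ``multi_copy`` (members with >=2 copies); the means
    across genomes are in ``frame.attrs["mean_present"]`` and
    ``attrs["mean_multi_copy"]``.
    """
    members = sorted(set(marker_set.cog_ids) - set(matrix.unsearchable))
    table = matrix.table(mode)[members]
    frame = pd.DataFrame({
        "present": (table >= 1).sum(axis=1),
        "multi_copy": (table >= 2).sum(axis=1),
    })
    frame.attrs["mean_present"] = float(frame["present"].mean())
    frame.attrs["mean_multi_copy"] = float(frame["multi_copy"].mean())
    return frame
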