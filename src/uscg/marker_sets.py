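"""Published universal single-copy gene (USCG) sets: loading and comparison.

A USCG set is a named collection of COG identifiers. Seven such sets from the
literature ship with the package as plain-text fixture lists (synthetic
stand-in transcriptions, see ``data/``); this module loads arbitrary lists in
the same one-id-per-line dialect, converts gene symbols to COG ids with a
COG definition table, computes pairwise set overlaps, and summarises each
set's functional-category composition (categories J, L, H, O, F and a pooled
"other" bucket).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import COG_ID_RE, CogAnnotation, logger, parse_cog_def_table

#: default order of reported functional categories (Fig-1B style)
REPORTED_CATEGORIES = ("J", "L", "H", "O", "F")

#: stems of the bundled synthetic stand-in fixture lists, in publication order
BUILTIN_SET_STEMS = (
    "ciccarelli2006.synthetic",
    "wu_eisen2008.synthetic",
    "creevey2011.synthetic",
    "wu2013.synthetic",
    "alneberg2014.synthetic",
    "lan2016.synthetic",
    "parks2018.synthetic",
)


@dataclass(frozen=True)
class MarkerSet:
    """A named, unordered, duplicate-free collection of COG identifiers."""

    name: str
    cog_ids: frozenset[str]
    citation: str = ""

    def __post_init__(self) -> None:
        if not self.cog_ids:
            raise ValueError(f"marker set {self.name!r} is empty")
        bad = [c for c in self.cog_ids if not COG_ID_RE.match(c)]
        if bad:
            raise ValueError(f"marker set {self.name!r}: malformed ids {sorted(bad)[:3]}")

    def __len__(self) -> int:
        return len(self.cog_ids)

    def __contains__(self, cog_id: str) -> bool:
        return cog_id in self.cog_ids


def load_marker_set(path: str | Path, name: str | None = None) -> MarkerSet:
    """Load one marker-set file: one COG id per line, ``#`` comments allowed.

    Identifiers are uppercased; duplicates are collapsed with a warning;
    a malformed identifier rejects the whole file with its line number.
    """
    path = Path(path)
    seen: list[str] = []
    citation = ""
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.strip()
        if line.startswith("#"):
            if lineno == 1:
                citation = line.lstrip("# ").strip()
            continue
        if not line:
            continue
        cog_id = line.upper()
        if not COG_ID_RE.match(cog_id):
            raise ValueError(f"{path}:{lineno}: malformed COG identifier {line!r}")
        if cog_id in seen:
            logger.warning("%s:%d: duplicate identifier %s collapsed", path.name, lineno, cog_id)
        else:
            seen.append(cog_id)
    if not seen:
        raise ValueError(f"{path}: no COG identifiers found")
    return MarkerSet(name or path.stem.split(".")[0], frozenset(seen), citation)


def load_marker_sets(paths: Iterable[str | Path]) -> list[MarkerSet]:
    return [load_marker_set(p) for p in paths]


def builtin_marker_sets() -> list[MarkerSet]:
    """The seven bundled USCG fixture sets, in publication order."""
    sets = []
    for stem in BUILTIN_SET_STEMS:
        ref = resources.files("uscg.data") / f"{stem}.txt"
        with resources.as_file(ref) as path:
            sets.append(load_marker_set(path))
    return sets


def builtin_cog_annotations() -> list[CogAnnotation]:
    """The bundled synthetic COG definition table."""
    ref = resources.files("uscg.data") / "cog-def.synthetic.tab"
    with resources.as_file(ref) as path:
        return parse_cog_def_table(path)


# ---------------------------------------------------------------------------
# Gene-symbol -> COG conversion
# ---------------------------------------------------------------------------

@dataclass
class NameMapping:
    """Result of converting gene symbols to COG ids.

    ``matched`` maps each resolved symbol to its unique COG id; ``unmatched``
    lists symbols absent from the table; ``ambiguous`` maps symbols found
    under several COG ids to the full candidate list (never resolved
    silently).
    """

    matched: dict[str, str] = field(default_factory=dict)
    unmatched: list[str] = field(default_factory=list)
    ambiguous: dict[str, list[str]] = field(default_factory=dict)


def map_names_to_cogs(gene_names: Iterable[str],
                      table: Sequence[CogAnnotation]) -> NameMapping:
    """Convert gene symbols to COG ids by exact, case-insensitive lookup."""
    by_symbol: dict[str, list[str]] = {}
    for ann in table:
        if ann.gene_symbol:
            by_symbol.setdefault(ann.gene_symbol.lower(), []).append(ann.cog_id)
    out = NameMapping()
    for name in gene_names:
        hits = sorted(set(by_symbol.get(name.lower(), [])))
        if not hits:
            out.unmatched.append(name)
        elif len(hits) > 1:
            out.ambiguous[name] = hits
        else:
            out.matched[name] = hits[0]
    if out.unmatched:
        logger.warning("%d gene name(s) not found in COG table: %s",
                       len(out.unmatched), out.unmatched[:5])
    if out.ambiguous:
        logger.warning("%d gene name(s) ambiguous in COG table: %s",
                       len(out.ambiguous), sorted(out.ambiguous)[:5])
    return out


# ---------------------------------------------------------------------------
# Set overlap
# ---------------------------------------------------------------------------

@dataclass
class OverlapMatrix:
    """Pairwise shared-identifier counts between marker sets.

    ``counts`` is a symmetric DataFrame whose diagonal holds each set's
    cardinality; ``shared_ids`` keeps the actual shared identifiers per
    unordered pair. Percentages are reported relative to the first-named set.
    """

    set_names: list[str]
    counts: pd.DataFrame
    shared_ids: dict[tuple[str, str], frozenset[str]]

    def count(self, a: str, b: str) -> int:
        return int(self.counts.loc[a, b])

    def percent(self, a: str, b: str) -> float:
        """Shared count as a percentage of set ``a``'s cardinality."""
        return 100.0 * self.count(a, b) / self.count(a, a)

    def to_frame(self) -> pd.DataFrame:
        return self.counts.copy()


def overlap_matrix(sets: Sequence[MarkerSet]) -> OverlapMatrix:
    """Exact pairwise shared-COG counts for two or more marker sets."""
    if len(sets) < 2:
        raise ValueError("need at least two marker sets to compare")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ValueError("marker-set names must be unique for comparison")
    counts = pd.DataFrame(0, index=names, columns=names, dtype=int)
    shared: dict[tuple[str, str], frozenset[str]] = {}
    for a, b in itertools.combinations_with_replacement(sets, 2):
        common = frozenset(a.cog_ids & b.cog_ids)
        counts.loc[a.name, b.name] = counts.loc[b.name, a.name] = len(common)
        shared[(a.name, b.name)] = shared[(b.name, a.name)] = common
    return OverlapMatrix(names, counts, shared)


# ---------------------------------------------------------------------------
# Functional-category composition
# ---------------------------------------------------------------------------

@dataclass
class CategoryComposition:
    """Per-category percentages for one marker set (sums to 100 over annotated members)."""

    set_name: str
    percentages: dict[str, float]
    n_annotated: int
    missing: list[str]

    def modal_category(self) -> str:
        return max(self.percentages, key=lambda c: self.percentages[c])


def category_composition(marker_set: MarkerSet,
                         annotations: Sequence[CogAnnotation],
                         categories: Sequence[str] = REPORTED_CATEGORIES,
                         ) -> CategoryComposition:
    """Percentage of a set's members in categories J, L, H, O, F and "other".

    A multi-letter annotation (e.g. ``"JK"``) contributes only its first
    letter, so every annotated member falls in exactly one bucket and the
    percentages sum to 100. Members missing from the table are excluded from
    the denominator and reported.
    """
    first_cat = {ann.cog_id: ann.categories[0] for ann in annotations}
    missing = sorted(c for c in marker_set.cog_ids if c not in first_cat)
    if missing:
        logger.warning("set %s: %d member(s) without annotation excluded: %s",
                       marker_set.name, len(missing), missing[:5])
    annotated = [c for c in marker_set.cog_ids if c in first_cat]
    tallies = {c: 0 for c in categories}
    tallies["other"] = 0
    for cog_id in annotated:
        cat = first_cat[cog_id]
        tallies[cat if cat in tallies else "other"] += 1
    n = len(annotated)
    if n == 0:
        raise ValueError(f"set {marker_set.name!r}: no annotated members")
    pct = {cat: 100.0 * k / n for cat, k in tallies.items()}
    return CategoryComposition(marker_set.name, pct, n, missing)


def composition_table(sets: Sequence[MarkerSet],
                      annotations: Sequence[CogAnnotation]) -> pd.DataFrame:
    """Fig-1B-style table: one row per set, one column per reported category."""
    rows = {}
    for s in sets:
        rows[s.name] = category_composition(s, annotations).percentages
    return pd.DataFrame(rows).T[list(REPORTED_CATEGORIES) + ["other"]]
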