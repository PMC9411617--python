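"""Readers/writers for the pipeline's file dialects, configuration and logging.

Formats handled here:

* protein FASTA (plain or aligned) via Biopython, with the pipeline's
  normalisation contract: ids are the first whitespace token of the header,
  sequences are uppercased, trailing ``*`` stop characters are stripped with
  a warning, and duplicate ids within one file are an error;
* the NCBI ``cog-20.def.tab`` dialect (tab-separated COG definitions);
* taxonomy tables (``genome_id  genus  species  strain  fasta_path``);
* a flat ``key = value`` configuration file mapped onto :class:`PipelineConfig`.

All genomic/protein coordinates written by this package are 0-based,
half-open; every TSV carries its column header.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("uscg")

COG_ID_RE = re.compile(r"^COG\d{4}$")


def setup_logging(level: int = logging.INFO) -> None:
    """Attach a stderr handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA file into an ordered ``{id: sequence}`` mapping.

    The record id is the first whitespace-separated token of the header.
    Sequences are uppercased; ``*`` characters (translation stops) are
    stripped with a warning. Duplicate ids raise ``ValueError`` naming the id.
    """
    path = Path(path)
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if "*" in seq:
            logger.warning("stripping '*' stop character(s) from %s in %s", rec.id, path.name)
            seq = seq.replace("*", "")
        if rec.id in records:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        records[rec.id] = seq
    return records


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    """Write ``{id: sequence}`` to FASTA with fixed line wrapping."""
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# COG definition table (cog-20.def.tab dialect)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CogAnnotation:
    """One row of a COG definition table.

    ``categories`` is the ordered list of single-letter functional-category
    codes (a multi-letter entry such as ``"JK"`` is split); ``gene_symbol``
    may be empty.
    """

    cog_id: str
    categories: tuple[str, ...]
    description: str = ""
    gene_symbol: str = ""

    def __post_init__(self) -> None:
        if not self.categories:
            raise ValueError(f"{self.cog_id}: empty category list")
        for c in self.categories:
            if not (len(c) == 1 and c.isalpha() and c.isupper()):
                raise ValueError(f"{self.cog_id}: bad category code {c!r}")


def parse_cog_def_table(path: str | Path) -> list[CogAnnotation]:
    """Parse a tab-separated ``cog-20.def.tab``-dialect file.

    Column 1 is the COG id, column 2 the functional-category letters and
    column 4 the gene symbol; extra trailing columns are tolerated. Rows
    whose first field does not look like a COG id are skipped with a warning.
    """
    path = Path(path)
    annotations: list[CogAnnotation] = []
    with open(path, encoding="utf-8", errors="replace") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            cog_id = fields[0].strip()
            if not COG_ID_RE.match(cog_id):
                logger.warning("%s:%d: skipping row with malformed COG id %r",
                               path.name, lineno, cog_id)
                continue
            cats = tuple(fields[1].strip()) if len(fields) > 1 else ()
            desc = fields[2].strip() if len(fields) > 2 else ""
            symbol = fields[3].strip() if len(fields) > 3 else ""
            try:
                annotations.append(CogAnnotation(cog_id, cats, desc, symbol))
            except ValueError as exc:
                logger.warning("%s:%d: %s; row skipped", path.name, lineno, exc)
    if not annotations:
        logger.warning("%s: no COG annotations parsed", path.name)
    return annotations


# ---------------------------------------------------------------------------
# Taxonomy tables and generic TSV helpers
# ---------------------------------------------------------------------------

def read_taxonomy_table(path: str | Path) -> pd.DataFrame:
    """Read a taxonomy TSV with columns genome_id/genus/species[/strain[/fasta_path]]."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    required = {"genome_id", "genus", "species"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"taxonomy table {path} lacks columns: {sorted(missing)}")
    if df["genome_id"].duplicated().any():
        dup = df.loc[df["genome_id"].duplicated(), "genome_id"].iloc[0]
        raise ValueError(f"duplicate genome_id {dup!r} in taxonomy table {path}")
    if "fasta_path" in df.columns:
        base = Path(path).parent
        df["fasta_path"] = [p if not p or Path(p).is_absolute() else str(base / p)
                            for p in df["fasta_path"]]
    return df


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Tunable parameters of the whole pipeline, with the published defaults.

    ``e_cutoff`` (1e-15) is the profile-search significance cutoff;
    ``pid_threshold_pct`` (99.5) the percent-identity limit beyond which
    two genomes are treated as indistinguishable; gap penalties are the
    conventional BLOSUM62 pairing (open 11, extend 1).
    """

    e_cutoff: float = 1e-15
    pid_threshold_pct: float = 99.5
    gap_open: float = 11.0
    gap_extend: float = 1.0
    pseudocount_weight: float = 1.0
    aggregation_mode: str = "concat"          # concat | mean
    pair_mode: str = "all"                    # all | representative
    uniqueness_denominator_mode: str = "all_genomes"  # all_genomes | present_genomes
    min_coverage_primary: float = 0.7
    min_coverage_rescue: float = 0.0
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def describe(self) -> str:
        items = dataclasses.asdict(self)
        return "; ".join(f"{k}={v}" for k, v in items.items() if k != "paths")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a flat ``key = value`` config file; unknown keys are an error."""
    cfg = PipelineConfig()
    fields = {f.name: f for f in dataclasses.fields(PipelineConfig)}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in fields or key == "paths":
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        ftype = fields[key].type
        if ftype in ("float", float):
            setattr(cfg, key, float(value))
        elif ftype in ("int", int):
            setattr(cfg, key, int(value))
        else:
            setattr(cfg, key, value)
    return cfg
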