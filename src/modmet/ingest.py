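"""Readers for genome annotations, quality, and metadata, plus derived
genome-architecture quantities.

Consumes the standard upstream outputs of a genome-resolved metagenomics
workflow: eggNOG-mapper annotation tables (KO assignments per predicted
gene), CheckM-style quality tables (completeness / contamination), GFF3
feature tables (for the noncoding fraction), and plain TSV genome / sample
metadata. Assembly, binning, annotation, and quality estimation themselves
are out of scope — their outputs are inputs here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeRecord",
    "SampleMetadata",
    "IngestError",
    "AnnotationSet",
    "read_annotations",
    "read_quality",
    "apply_quality_filter",
    "compute_egs",
    "compute_noncoding_fraction",
    "read_genome_metadata",
    "read_sample_metadata",
    "build_genome_records",
]


class IngestError(ValueError):
    """Raised on malformed input tables."""


@dataclass
class GenomeRecord:
    """One genome (MAG or SAG): identity, architecture, and KO content.

    ``egs_bp`` is the completeness-corrected estimated genome size;
    ``noncoding_fraction`` is optional (requires a feature table).
    """

    genome_id: str
    taxonomy: dict[str, str]
    gc_percent: float
    genome_size_bp: int
    completeness_percent: float
    contamination_percent: float
    egs_bp: float
    ko_set: set[str] = field(default_factory=set)
    n_genes: int = 0
    noncoding_fraction: float | None = None
    source_type: str = "MAG"

    @property
    def phylum(self) -> str:
        return self.taxonomy.get("phylum", "unclassified")


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    borehole_id: str
    depth_mbsl: float
    salinity_ppt: float | None = None

    def __post_init__(self) -> None:
        if not self.borehole_id:
            raise IngestError("borehole_id must be non-empty")
        if self.depth_mbsl < 0:
            raise IngestError(f"negative depth for sample {self.sample_id}")


@dataclass
class AnnotationSet:
    """Per-genome KO sets plus gene totals (needed for SAP normalization)."""

    ko_sets: dict[str, set[str]]
    gene_counts: dict[str, int]
    #: per-genome multiset of KO tokens, one entry per annotated gene copy
    gene_kos: dict[str, list[str]]

    def genomes(self) -> list[str]:
        return sorted(self.ko_sets)


def read_annotations(path: str | Path, genome_column: str | None = None) -> AnnotationSet:
    """Parse an eggNOG-mapper annotations table into per-genome KO sets.

    The dialect: comment lines start with ``#`` (the last one before data
    holds the column names), a ``KEGG_ko`` column carries comma-separated
    ``ko:Kxxxxx`` tokens with ``-`` meaning no assignment. Genome identity
    comes from *genome_column* if given, otherwise from the query name
    prefix before the last ``_``.

    KO tokens are stripped of their ``ko:`` prefix and de-duplicated per
    genome; genes without a KO still count toward the per-genome gene total.
    """
    path = Path(path)
    header: list[str] | None = None
    ko_sets: dict[str, set[str]] = {}
    gene_counts: dict[str, int] = {}
    gene_kos: dict[str, list[str]] = {}
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                header = line.lstrip("#").strip().split("\t")
                continue
            if header is None:
                raise IngestError(f"{path}: data before header line")
            if "KEGG_ko" not in header:
                raise IngestError(f"{path}: missing KEGG_ko column")
            cells = line.split("\t")
            row = dict(zip(header, cells))
            query = row.get("query", cells[0])
            if genome_column and genome_column in row:
                genome = row[genome_column]
            else:
                genome = query.rsplit("_", 1)[0]
            gene_counts[genome] = gene_counts.get(genome, 0) + 1
            ko_sets.setdefault(genome, set())
            gene_kos.setdefault(genome, [])
            cell = row.get("KEGG_ko", "-").strip()
            if cell in ("-", ""):
                continue
            for tok in cell.split(","):
                tok = tok.strip()
                if tok.startswith("ko:"):
                    tok = tok[3:]
                if tok:
                    ko_sets[genome].add(tok)
                    gene_kos[genome].append(tok)
    return AnnotationSet(ko_sets=ko_sets, gene_counts=gene_counts, gene_kos=gene_kos)


def read_quality(path: str | Path) -> pd.DataFrame:
    """Read a CheckM-style quality table.

    Accepts ``genome_id``/``Bin Id``/``bin_id`` for the identifier and
    case-insensitive ``completeness`` / ``contamination`` columns. Returns a
    DataFrame indexed by genome_id with float columns.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower().replace(" ", "_"): c for c in df.columns}
    id_col = next((cols[k] for k in ("genome_id", "bin_id") if k in cols), None)
    comp_col = cols.get("completeness")
    cont_col = cols.get("contamination")
    if id_col is None or comp_col is None or cont_col is None:
        raise IngestError(f"{path}: need genome/bin id, completeness, contamination columns")
    out = df[[id_col, comp_col, cont_col]].copy()
    out.columns = ["genome_id", "completeness", "contamination"]
    for col in ("completeness", "contamination"):
        vals = pd.to_numeric(out[col], errors="coerce")
        bad = out.loc[vals.isna() & out[col].notna(), "genome_id"]
        if len(bad):
            raise IngestError(f"{path}: non-numeric {col} for {bad.iloc[0]}")
        out[col] = vals
    return out.set_index("genome_id")


def apply_quality_filter(
    quality: pd.DataFrame,
    min_completeness: float = 50.0,
    max_contamination: float = 5.0,
) -> pd.DataFrame:
    """Keep genomes with completeness ≥ 50% and contamination ≤ 5% (defaults).

    The number of discarded genomes is logged.
    """
    keep = (quality["completeness"] >= min_completeness) & (
        quality["contamination"] <= max_contamination
    )
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("quality filter discarded %d of %d genomes", n_drop, len(quality))
    return quality.loc[keep]


def compute_egs(
    genome_size_bp: float,
    completeness_percent: float,
    contamination_percent: float = 0.0,
    correct_contamination: bool = True,
) -> float:
    """Completeness-corrected estimated genome size.

    ``egs = size * (1 - contamination/100) / (completeness/100)``; the
    contamination correction in the numerator can be switched off to get the
    plain completeness scaling.
    """
    if genome_size_bp <= 0:
        raise IngestError("genome size must be positive")
    if not 0 < completeness_percent <= 100:
        raise IngestError(f"completeness out of (0,100]: {completeness_percent}")
    if not 0 <= contamination_percent < 100:
        raise IngestError(f"contamination out of [0,100): {contamination_percent}")
    numerator = genome_size_bp
    if correct_contamination:
        numerator *= 1.0 - contamination_percent / 100.0
    return numerator / (completeness_percent / 100.0)


def compute_noncoding_fraction(
    feature_intervals: list[tuple[str, int, int]] | list[tuple[int, int]],
    sequence_lengths: dict[str, int] | int,
) -> float:
    """Fraction of the assembly not covered by annotated features.

    Intervals are 1-based inclusive (GFF3 convention) and may carry a
    sequence name as first element; overlapping intervals are merged before
    summation. Strand is ignored. Intervals beyond a sequence end are an
    error.
    """
    if isinstance(sequence_lengths, int):
        seq_lens = {"": sequence_lengths}
    else:
        seq_lens = dict(sequence_lengths)
    total_bp = sum(seq_lens.values())
    if total_bp <= 0:
        raise IngestError("total sequence length must be positive")
    by_seq: dict[str, list[tuple[int, int]]] = {}
    for iv in feature_intervals:
        if len(iv) == 3:
            seq, start, end = iv  # type: ignore[misc]
        else:
            start, end = iv  # type: ignore[misc]
            seq = ""
        if seq not in seq_lens:
            raise IngestError(f"interval on unknown sequence {seq!r}")
        if start < 1 or end > seq_lens[seq]:
            raise IngestError(f"interval ({start},{end}) outside sequence {seq!r}")
        if end < start:
            raise IngestError(f"inverted interval ({start},{end})")
        by_seq.setdefault(seq, []).append((start, end))
    coding = 0
    for ivs in by_seq.values():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                coding += cur_e - cur_s + 1
                cur_s, cur_e = s, e
        coding += cur_e - cur_s + 1
    return 1.0 - coding / total_bp


def read_genome_metadata(path: str | Path) -> pd.DataFrame:
    """Genome metadata TSV: genome_id, taxonomy (``p__X;c__Y`` string),
    gc_percent, genome_size_bp, source_type."""
    df = pd.read_csv(path, sep="\t")
    required = {"genome_id", "taxonomy", "gc_percent", "genome_size_bp"}
    missing = required - set(df.columns)
    if missing:
        raise IngestError(f"{path}: missing columns {sorted(missing)}")
    if "source_type" not in df.columns:
        df["source_type"] = "MAG"
    return df.set_index("genome_id")


def parse_taxonomy(tax_string: str) -> dict[str, str]:
    """Parse a GTDB-style lineage string (``d__...;p__...;c__...``)."""
    prefix_map = {"d": "domain", "p": "phylum", "c": "class", "o": "order",
                  "f": "family", "g": "genus", "s": "species"}
    out: dict[str, str] = {}
    for part in str(tax_string).split(";"):
        part = part.strip()
        if "__" in part:
            pref, name = part.split("__", 1)
            rank = prefix_map.get(pref)
            if rank and name:
                out[rank] = name
    return out


def read_sample_metadata(path: str | Path) -> dict[str, SampleMetadata]:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "borehole_id", "depth_mbsl"}
    missing = required - set(df.columns)
    if missing:
        raise IngestError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, SampleMetadata] = {}
    for _, row in df.iterrows():
        sal = float(row["salinity_ppt"]) if "salinity_ppt" in df.columns else None
        out[str(row["sample_id"])] = SampleMetadata(
            sample_id=str(row["sample_id"]),
            borehole_id=str(row["borehole_id"]),
            depth_mbsl=float(row["depth_mbsl"]),
            salinity_ppt=sal,
        )
    return out


def build_genome_records(
    metadata: pd.DataFrame,
    quality: pd.DataFrame,
    annotations: AnnotationSet,
    apply_filter: bool = True,
    correct_contamination: bool = True,
) -> list[GenomeRecord]:
    """Join metadata + quality + annotations into validated GenomeRecords.

    Genomes missing from the quality table are dropped with a warning (never
    defaulted — silent defaults would corrupt EGS estimates).
    """
    if apply_filter:
        quality = apply_quality_filter(quality)
    records: list[GenomeRecord] = []
    for genome_id, row in metadata.iterrows():
        if genome_id not in quality.index:
            warnings.warn(f"genome {genome_id} missing from quality table; dropped")
            continue
        comp = float(quality.loc[genome_id, "completeness"])
        cont = float(quality.loc[genome_id, "contamination"])
        size = int(row["genome_size_bp"])
        records.append(
            GenomeRecord(
                genome_id=str(genome_id),
                taxonomy=parse_taxonomy(row["taxonomy"]),
                gc_percent=float(row["gc_percent"]),
                genome_size_bp=size,
                completeness_percent=comp,
                contamination_percent=cont,
                egs_bp=compute_egs(size, comp, cont, correct_contamination),
                ko_set=set(annotations.ko_sets.get(str(genome_id), set())),
                n_genes=annotations.gene_counts.get(str(genome_id), 0),
                source_type=str(row.get("source_type", "MAG")),
            )
        )
    return records
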