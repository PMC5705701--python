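"""Readers and writers for the pipeline's external tables.

Supported formats: tab-separated junction-evidence tables, a BED-like
exon table (or GTF via :func:`read_exons_gtf`), RepeatMasker-style repeat
tables, bedGraph conservation tracks, BED element intervals, miRNA target
site tables, clinical tables, gene-expression matrices and a YAML run
configuration.  Every reader validates records and reports malformed rows
with their line number; every table has a matching writer so round-trips
are exact.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
import yaml

from .intervals import ConservationTrack, GenomicInterval

ALLOWED_REGIONS = ("CDS", "UTR5", "UTR3", "ncRNA")

_ALU_RE = re.compile(r"^(Alu[JSY])")


class FormatError(ValueError):
    """A malformed input file (missing columns, bad coordinates, ...)."""


class JunctionEvidence(NamedTuple):
    """One sample's read support for one (back)splice junction."""

    chrom: str
    start: int
    end: int
    strand: str
    sample_id: str
    n_reads: int
    mapq_anchor1: float | None = None
    mapq_anchor2: float | None = None

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def key(self) -> tuple[str, int, int, str]:
        """Backsplice identity: (chrom, start, end, strand)."""
        return (self.chrom, self.start, self.end, self.strand)


JUNCTION_COLUMNS = ["chrom", "start", "end", "strand", "sample_id", "n_reads"]
MAPQ_COLUMNS = ["mapq_anchor1", "mapq_anchor2"]


def read_junction_table(path: str | Path, kind: str = "circular") -> list[JunctionEvidence]:
    """Read a junction-evidence TSV into validated records.

    ``kind`` is "circular" (anchor MAPQ columns required) or "linear"
    (MAPQ columns optional).  Coordinates in the file are 0-based
    half-open.  Malformed rows raise :class:`FormatError` naming the
    offending line.
    """
    if kind not in ("circular", "linear"):
        raise ValueError(f"kind must be 'circular' or 'linear', got {kind!r}")
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in JUNCTION_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        has_mapq = all(c in header for c in MAPQ_COLUMNS)
        if kind == "circular" and not has_mapq:
            raise FormatError(
                f"{path}: circular junction table requires columns {MAPQ_COLUMNS}"
            )
        col = {name: header.index(name) for name in header}
        records: list[JunctionEvidence] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            try:
                start = int(fields[col["start"]])
                end = int(fields[col["end"]])
                n_reads = int(fields[col["n_reads"]])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start ({start}) must be < end ({end})"
                )
            if n_reads < 0:
                raise FormatError(f"{path}:{lineno}: negative read count")
            mq1 = mq2 = None
            if has_mapq:
                raw1 = fields[col["mapq_anchor1"]]
                raw2 = fields[col["mapq_anchor2"]]
                mq1 = float(raw1) if raw1 not in ("", "NA") else None
                mq2 = float(raw2) if raw2 not in ("", "NA") else None
                for mq in (mq1, mq2):
                    if mq is not None and mq < 0:
                        raise FormatError(f"{path}:{lineno}: negative MAPQ")
            records.append(
                JunctionEvidence(
                    chrom=fields[col["chrom"]],
                    start=start,
                    end=end,
                    strand=fields[col["strand"]],
                    sample_id=fields[col["sample_id"]],
                    n_reads=n_reads,
                    mapq_anchor1=mq1,
                    mapq_anchor2=mq2,
                )
            )
    return records


def write_junction_table(
    records: Iterable[JunctionEvidence], path: str | Path, with_mapq: bool = True
) -> None:
    path = Path(path)
    cols = JUNCTION_COLUMNS + (MAPQ_COLUMNS if with_mapq else [])
    with path.open("w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            row = [r.chrom, str(r.start), str(r.end), r.strand, r.sample_id, str(r.n_reads)]
            if with_mapq:
                row += [
                    "NA" if r.mapq_anchor1 is None else f"{r.mapq_anchor1:g}",
                    "NA" if r.mapq_anchor2 is None else f"{r.mapq_anchor2:g}",
                ]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# annotation inputs


EXON_COLUMNS = [
    "chrom", "start", "end", "strand", "gene_id", "transcript_id",
    "exon_number", "region",
]


def read_exon_table(path: str | Path) -> pd.DataFrame:
    """BED-like exon table (0-based half-open) with region labels."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in EXON_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    bad = df.index[~df["region"].isin(ALLOWED_REGIONS)]
    if len(bad):
        label = df.loc[bad[0], "region"]
        raise FormatError(
            f"{path}: unknown region label {label!r}; allowed: {list(ALLOWED_REGIONS)}"
        )
    if (df["start"] >= df["end"]).any():
        lineno = int(df.index[df["start"] >= df["end"]][0]) + 2
        raise FormatError(f"{path}:{lineno}: start >= end")
    return df[EXON_COLUMNS].copy()


def read_exons_gtf(path: str | Path) -> pd.DataFrame:
    """Read exon features from a GTF file into the internal exon table.

    GTF coordinates are 1-based inclusive and are converted to 0-based
    half-open here.  The region label is taken from a ``region``
    attribute when present, else CDS for protein-coding exons is not
    inferable from a bare exon line and the label defaults to ``ncRNA``.
    """
    rows = []
    attr_re = re.compile(r'(\w+) "([^"]*)"')
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF fields")
            if parts[2] != "exon":
                continue
            attrs = dict(attr_re.findall(parts[8]))
            rows.append(
                {
                    "chrom": parts[0],
                    "start": int(parts[3]) - 1,  # 1-based inclusive -> 0-based
                    "end": int(parts[4]),
                    "strand": parts[6],
                    "gene_id": attrs.get("gene_id", ""),
                    "transcript_id": attrs.get("transcript_id", ""),
                    "exon_number": int(attrs.get("exon_number", 0)),
                    "region": attrs.get("region", "ncRNA"),
                }
            )
    df = pd.DataFrame(rows, columns=EXON_COLUMNS)
    bad = ~df["region"].isin(ALLOWED_REGIONS)
    if bad.any():
        label = df.loc[bad.idxmax(), "region"]
        raise FormatError(
            f"{path}: unknown region label {label!r}; allowed: {list(ALLOWED_REGIONS)}"
        )
    return df


def alu_subfamily(repeat_name: str) -> str | None:
    """Map a RepeatMasker repeat name to its Alu subfamily class.

    "AluJb" -> "AluJ"; "AluSx1" -> "AluS"; "AluYa5" -> "AluY"; any
    non-Alu name (or an Alu without a family letter) -> None.
    """
    m = _ALU_RE.match(repeat_name)
    return m.group(1) if m else None


def read_repeat_table(path: str | Path) -> pd.DataFrame:
    """RepeatMasker-style repeat table; adds the ``subfamily`` column."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["chrom", "start", "end", "strand", "repeat_name"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    df = df[required].copy()
    df["subfamily"] = df["repeat_name"].map(lambda n: alu_subfamily(str(n)))
    return df


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """BED3+ intervals (0-based half-open); strand from column 6 if present."""
    out: list[GenomicInterval] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            strand = parts[5] if len(parts) >= 6 and parts[5] in "+-" else "."
            try:
                out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_bedgraph(path: str | Path) -> ConservationTrack:
    records = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: bedGraph needs 4 columns")
            try:
                records.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return ConservationTrack.from_records(records)


def write_bedgraph(track: ConservationTrack, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for chrom, start, end, value in track.to_bedgraph_records():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.4f}\n")


MIRNA_COLUMNS = ["chrom", "start", "end", "mirna_id", "experiment_id", "conserved"]


def read_mirna_sites(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = MIRNA_COLUMNS[:5]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if "conserved" not in df.columns:
        df["conserved"] = True
    return df[MIRNA_COLUMNS].copy()


CLINICAL_COLUMNS = [
    "sample_id", "risk_class", "stage", "grade", "eortc_score",
    "library_size", "time_months", "progressed",
]


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if (df["time_months"] <= 0).any():
        raise FormatError(f"{path}: time_months must be positive")
    return df[CLINICAL_COLUMNS].copy()


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Gene x sample expression matrix, first column = gene_id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.6g")


# ---------------------------------------------------------------------------
# run configuration and the annotation bundle


@dataclass
class RunConfig:
    """All thresholds and input paths for one pipeline run.

    Threshold defaults follow the source study: anchor MAPQ cutoff 35,
    robust tier >= 2 reads in >= 2 samples, abundant tier expressed in
    >= 30 samples with >= 20 reads in at least one, FDR level 0.1,
    20 kb Alu flanks, a 6 bp window around splice sites, and a 10 kb
    length cap for non-exonic circRNAs in the miRNA analysis.
    """

    # thresholds
    min_reads: int = 2
    min_samples_robust: int = 2
    abundant_min_samples: int = 30
    abundant_min_reads: int = 20
    mapq_cutoff: float = 35.0
    fdr_level: float = 0.1
    alu_window_bp: int = 20_000
    splice_window_bp: int = 6
    mirna_max_circ_len_bp: int = 10_000
    log2fc_pseudocount_cpm: float = 1.0
    allow_missing_mapq: bool = False
    seed: int = 0
    # input paths (None = stage skipped where optional)
    circ_junctions: str | None = None
    linear_junctions: str | None = None
    exons: str | None = None
    repeats: str | None = None
    conservation: str | None = None
    sce: str | None = None
    mirna_sites: str | None = None
    gene_expression: str | None = None
    clinical: str | None = None
    # gene ids of the biogenesis regulators in the expression matrix
    adar_gene: str = "ADAR1"
    qki_gene: str = "QKI"

    def __post_init__(self) -> None:
        for name in (
            "min_reads", "min_samples_robust", "abundant_min_samples",
            "abundant_min_reads", "alu_window_bp", "splice_window_bp",
            "mirna_max_circ_len_bp",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mapq_cutoff < 0:
            raise ValueError("mapq_cutoff must be >= 0")
        if not (0 < self.fdr_level < 1):
            raise ValueError("fdr_level must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class AnnotationBundle:
    """All annotation tracks needed by the characterization stages."""

    exons: pd.DataFrame
    repeats: pd.DataFrame | None = None
    conservation: ConservationTrack | None = None
    sce: list[GenomicInterval] = field(default_factory=list)
    mirna_sites: pd.DataFrame | None = None

    @property
    def alu_repeats(self) -> pd.DataFrame:
        """Repeats with a recognized Alu subfamily class."""
        if self.repeats is None:
            return pd.DataFrame(
                columns=["chrom", "start", "end", "strand", "repeat_name", "subfamily"]
            )
        return self.repeats[self.repeats["subfamily"].notna()].reset_index(drop=True)


def read_annotation_bundle(config: RunConfig) -> AnnotationBundle:
    """Load every configured annotation input into one bundle."""
    if config.exons is None:
        raise FormatError("config.exons is required to build an annotation bundle")
    exon_path = Path(config.exons)
    if exon_path.suffix.lower() in (".gtf", ".gff"):
        exons = read_exons_gtf(exon_path)
    else:
        exons = read_exon_table(exon_path)
    repeats = read_repeat_table(config.repeats) if config.repeats else None
    conservation = read_bedgraph(config.conservation) if config.conservation else None
    sce = read_bed(config.sce) if config.sce else []
    mirna = read_mirna_sites(config.mirna_sites) if config.mirna_sites else None
    return AnnotationBundle(
        exons=exons,
        repeats=repeats,
        conservation=conservation,
        sce=sce,
        mirna_sites=mirna,
    )
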