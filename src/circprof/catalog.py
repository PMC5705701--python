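"""circRNA catalog construction, filtering, quantification and ratios.

A circRNA's identity is the (chrom, start, end, strand) of its backsplice
junction.  Catalog tiers:

* detected — supported by >= ``min_reads`` backsplice reads in at least
  one sample;
* robust   — >= ``min_reads`` in at least ``min_samples`` different
  samples (the working set for all downstream analyses);
* abundant — expressed in >= 30 samples and supported by >= 20 reads in
  at least one sample (the highly expressed set that is characterized
  and triaged).

Counts are normalized to CPM against each sample's total mapped library
size, and the circular-to-linear ratio per sample is
(circ reads + 1) / (linear reads + 1), the pseudocount avoiding division
by zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalIndex
from .io import JunctionEvidence


def circ_id(chrom: str, start: int, end: int, strand: str) -> str:
    return f"{chrom}:{start}-{end}({strand})"


@dataclass
class CircCatalog:
    """Unique backsplice junctions with tier flags.

    ``table`` columns: circ_id, chrom, start, end, strand, n_samples,
    total_reads, max_reads, detected, robust.  Rows are ordered
    lexicographically by (chrom, start, end, strand) so output is
    reproducible.
    """

    table: pd.DataFrame

    def intervals(self, tier: str = "robust") -> dict[str, GenomicInterval]:
        sub = self.table[self.table[tier]] if tier in ("detected", "robust") else self.table
        return {
            row.circ_id: GenomicInterval(row.chrom, row.start, row.end, row.strand)
            for row in sub.itertuples()
        }


def filter_junctions(
    evidence: list[JunctionEvidence],
    mapq_cutoff: float,
    allow_missing_mapq: bool = False,
) -> list[JunctionEvidence]:
    """Keep records whose two anchor MAPQs are both >= the cutoff.

    The comparison is inclusive.  Records without MAPQ fields pass only
    when ``allow_missing_mapq`` (pre-filtered input); otherwise they are
    dropped.
    """
    kept = []
    for rec in evidence:
        mqs = (rec.mapq_anchor1, rec.mapq_anchor2)
        if any(m is not None and m < 0 for m in mqs):
            raise ValueError(f"negative MAPQ in record {rec}")
        if None in mqs:
            if allow_missing_mapq:
                kept.append(rec)
            continue
        if mqs[0] >= mapq_cutoff and mqs[1] >= mapq_cutoff:
            kept.append(rec)
    return kept


def _evidence_counts(evidence: list[JunctionEvidence]) -> pd.DataFrame:
    """Pivot evidence into a junction x sample read-count matrix."""
    if not evidence:
        return pd.DataFrame()
    df = pd.DataFrame(
        {
            "key": [circ_id(*r.key) for r in evidence],
            "chrom": [r.chrom for r in evidence],
            "start": [r.start for r in evidence],
            "end": [r.end for r in evidence],
            "strand": [r.strand for r in evidence],
            "sample_id": [r.sample_id for r in evidence],
            "n_reads": [r.n_reads for r in evidence],
        }
    )
    counts = (
        df.pivot_table(
            index=["chrom", "start", "end", "strand"],
            columns="sample_id",
            values="n_reads",
            aggfunc="sum",
            fill_value=0,
        )
        .sort_index()
    )
    return counts


def build_catalog(
    evidence: list[JunctionEvidence],
    min_reads: int = 2,
    min_samples: int = 2,
    sample_ids: list[str] | None = None,
) -> tuple[CircCatalog, pd.DataFrame]:
    """Build the catalog and the robust-tier count matrix.

    Returns ``(catalog, counts)`` where ``counts`` is circ_id x sample
    over the robust set.  ``sample_ids`` fixes the column universe (e.g.
    every sample in the cohort, including all-zero ones); by default the
    samples observed in the evidence are used.
    """
    counts = _evidence_counts(evidence)
    if counts.empty:
        empty = pd.DataFrame(
            columns=[
                "circ_id", "chrom", "start", "end", "strand",
                "n_samples", "total_reads", "max_reads", "detected", "robust",
            ]
        )
        return CircCatalog(empty), pd.DataFrame(columns=sample_ids or [])
    support = (counts >= min_reads).sum(axis=1)
    table = pd.DataFrame(
        {
            "chrom": counts.index.get_level_values("chrom"),
            "start": counts.index.get_level_values("start"),
            "end": counts.index.get_level_values("end"),
            "strand": counts.index.get_level_values("strand"),
            "n_samples": (counts > 0).sum(axis=1).to_numpy(),
            "total_reads": counts.sum(axis=1).to_numpy(),
            "max_reads": counts.max(axis=1).to_numpy(),
            "detected": (support >= 1).to_numpy(),
            "robust": (support >= min_samples).to_numpy(),
        }
    )
    table.insert(
        0,
        "circ_id",
        [circ_id(c, s, e, st) for c, s, e, st in zip(
            table.chrom, table.start, table.end, table.strand)],
    )
    table = table.reset_index(drop=True)

    robust_mask = table["robust"].to_numpy()
    robust_counts = counts[robust_mask]
    robust_counts.index = table.loc[robust_mask, "circ_id"].to_numpy()
    robust_counts.index.name = "circ_id"
    robust_counts.columns.name = None
    if sample_ids is not None:
        robust_counts = robust_counts.reindex(columns=sample_ids, fill_value=0)
    robust_counts = robust_counts.sort_index(axis=1)
    return CircCatalog(table), robust_counts.astype(int)


def cpm_normalize(counts: pd.DataFrame, library_sizes: pd.Series) -> pd.DataFrame:
    """Counts per million against per-sample total mapped library size."""
    libs = library_sizes.reindex(counts.columns)
    if libs.isna().any():
        missing = list(libs.index[libs.isna()])
        raise ValueError(f"missing library sizes for samples {missing}")
    return counts / libs * 1e6


def flag_abundant(
    counts: pd.DataFrame,
    min_samples: int = 30,
    min_reads: int = 20,
    expressed_min_reads: int = 2,
) -> set[str]:
    """circ_ids expressed in >= ``min_samples`` samples with >=
    ``min_reads`` reads in at least one sample.

    "Expressed in a sample" means a count of at least
    ``expressed_min_reads`` (the detection support threshold).
    """
    if counts.empty:
        return set()
    expressed = (counts >= expressed_min_reads).sum(axis=1) >= min_samples
    supported = counts.max(axis=1) >= min_reads
    return set(counts.index[expressed & supported])


def linear_counterpart(
    linear_evidence: list[JunctionEvidence],
    catalog: CircCatalog,
    sample_ids: list[str],
) -> pd.DataFrame:
    """Per circRNA per sample, linear spliced reads using the same sites.

    A circle's acceptor site is its backsplice start; its donor site is
    its backsplice end.  Linear junctions ending at the acceptor plus
    linear junctions starting at the donor contribute their reads; each
    site contributes its own count.  Strands must agree when both are
    stranded.
    """
    by_end: dict[tuple[str, int], list[JunctionEvidence]] = {}
    by_start: dict[tuple[str, int], list[JunctionEvidence]] = {}
    for rec in linear_evidence:
        by_end.setdefault((rec.chrom, rec.end), []).append(rec)
        by_start.setdefault((rec.chrom, rec.start), []).append(rec)

    robust = catalog.table[catalog.table["robust"]]
    out = pd.DataFrame(
        0, index=robust["circ_id"].to_numpy(), columns=sorted(sample_ids), dtype=int
    )
    out.index.name = "circ_id"
    sample_pos = {s: i for i, s in enumerate(out.columns)}
    values = out.to_numpy()
    for i, row in enumerate(robust.itertuples()):
        matches = by_end.get((row.chrom, row.start), []) + by_start.get(
            (row.chrom, row.end), []
        )
        for rec in matches:
            if (
                row.strand in "+-"
                and rec.strand in "+-"
                and rec.strand != row.strand
            ):
                continue
            j = sample_pos.get(rec.sample_id)
            if j is not None:
                values[i, j] += rec.n_reads
    return pd.DataFrame(values, index=out.index, columns=out.columns)


def circ_to_lin(circ_counts: pd.DataFrame, linear_counts: pd.DataFrame) -> pd.DataFrame:
    """Elementwise (circ + 1) / (linear + 1)."""
    if circ_counts.shape != linear_counts.shape or not (
        circ_counts.index.equals(linear_counts.index)
        and circ_counts.columns.equals(linear_counts.columns)
    ):
        raise ValueError("circular and linear count matrices are not aligned")
    return (circ_counts + 1) / (linear_counts + 1)


def per_gene_profile(
    counts: pd.DataFrame, catalog: CircCatalog, exons: pd.DataFrame
) -> pd.DataFrame:
    """Distinct circRNAs and total circular reads per gene.

    A circRNA is assigned to every gene whose span it overlaps (and
    flagged ambiguous when that is more than one); circles overlapping no
    gene are grouped under "intergenic".
    """
    spans = (
        exons.groupby("gene_id")
        .agg(chrom=("chrom", "first"), start=("start", "min"), end=("end", "max"))
        .reset_index()
    )
    gene_ivs = [
        GenomicInterval(r.chrom, r.start, r.end) for r in spans.itertuples()
    ]
    index = IntervalIndex.build(gene_ivs, payloads=list(spans["gene_id"]))

    totals = counts.sum(axis=1)
    rows: dict[str, dict] = {}
    robust = catalog.table[catalog.table["robust"]]
    for row in robust.itertuples():
        if row.circ_id not in totals.index:
            continue
        genes = index.overlapping(row.chrom, row.start, row.end)
        ambiguous = len(genes) > 1
        for gene in genes or ["intergenic"]:
            entry = rows.setdefault(
                gene, {"n_distinct_circ": 0, "total_circ_reads": 0, "n_ambiguous": 0}
            )
            entry["n_distinct_circ"] += 1
            entry["total_circ_reads"] += int(totals[row.circ_id])
            entry["n_ambiguous"] += int(ambiguous)
    profile = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    profile.index.name = "gene_id"
    return profile
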