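"""SCE and miRNA target-site enrichment of circularized coding exons.

The exon universe is the genome-wide set of collapsed exons.  Coding
exons are those with >= 90% of their bases in CDS annotation; a coding
exon is "circularized" when fully contained in a circRNA's backsplice
span.  Exons are assigned hierarchically — abundant circRNA >
non-abundant circRNA > linear-only — and element containment, coverage,
and observed-vs-expected statistics are computed per group and per
abundant circRNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import (
    GenomicInterval,
    IntervalIndex,
    merge_intervals,
    merge_spans,
    overlap_length_with_set,
    total_length,
)


@dataclass
class CodingExonGroups:
    """Disjoint hierarchical assignment of collapsed coding exons."""

    abundant_circ: list[GenomicInterval]
    nonabundant_circ: list[GenomicInterval]
    linear_only: list[GenomicInterval]

    def __post_init__(self) -> None:
        sets = [set(self.abundant_circ), set(self.nonabundant_circ), set(self.linear_only)]
        n_union = len(sets[0] | sets[1] | sets[2])
        n_total = sum(len(s) for s in sets)
        if n_union != n_total:
            raise ValueError("coding exon groups are not disjoint")

    def as_dict(self) -> dict[str, list[GenomicInterval]]:
        return {
            "abundant_circ": self.abundant_circ,
            "nonabundant_circ": self.nonabundant_circ,
            "linear_only": self.linear_only,
        }


@dataclass
class EnrichmentExpectation:
    """Per-bp rates and totals behind the expected-overlap formulas."""

    p_sce: float = float("nan")
    l_sce: int = 0
    l_coding_exons: int = 0
    p_mirna: float = float("nan")
    t_mirnas: int = 0
    l_exons: int = 0


@dataclass
class SpongeStat:
    circ_id: str
    best_mirna: str = ""
    best_experiment: str = ""
    max_same_mirna_sites: int = 0


def collapse_exons(exons: pd.DataFrame) -> list[GenomicInterval]:
    """Union of exon records per (chrom, strand)."""
    out: list[GenomicInterval] = []
    for (chrom, strand), grp in exons.groupby(["chrom", "strand"]):
        for s, e in merge_spans(zip(grp["start"], grp["end"])):
            out.append(GenomicInterval(chrom, s, e, strand))
    return sorted(out)


def _strand_compatible(a: str, b: str) -> bool:
    return a == "." or b == "." or a == b


def build_coding_exon_groups(
    exons: pd.DataFrame,
    circ_intervals: dict[str, GenomicInterval],
    abundant_ids: set[str],
    min_cds_fraction: float = 0.9,
) -> tuple[CodingExonGroups, dict[str, list[GenomicInterval]]]:
    """Hierarchically grouped collapsed coding exons.

    Returns the groups plus a map circ_id -> the coding exons fully
    contained in that circle's span (used downstream for per-circle
    observed/expected overlap).
    """
    collapsed = collapse_exons(exons)
    cds_union = merge_intervals(
        GenomicInterval(r.chrom, r.start, r.end)
        for r in exons[exons["region"] == "CDS"].itertuples()
    )
    coding = [
        ex
        for ex in collapsed
        if overlap_length_with_set(ex, cds_union) >= min_cds_fraction * ex.length
    ]
    coding_index = IntervalIndex.build(coding, payloads=coding)

    per_circ: dict[str, list[GenomicInterval]] = {}
    in_abundant: set[GenomicInterval] = set()
    in_nonabundant: set[GenomicInterval] = set()
    for cid in sorted(circ_intervals):
        circ = circ_intervals[cid]
        contained = [
            ex
            for ex in coding_index.overlapping(circ.chrom, circ.start, circ.end)
            if ex.start >= circ.start
            and ex.end <= circ.end
            and _strand_compatible(ex.strand, circ.strand)
        ]
        per_circ[cid] = sorted(contained)
        target = in_abundant if cid in abundant_ids else in_nonabundant
        target.update(contained)
    in_nonabundant -= in_abundant  # abundant takes precedence
    linear = [ex for ex in coding if ex not in in_abundant and ex not in in_nonabundant]
    groups = CodingExonGroups(
        abundant_circ=sorted(in_abundant),
        nonabundant_circ=sorted(in_nonabundant),
        linear_only=sorted(linear),
    )
    return groups, per_circ


def containment_fractions(
    groups: CodingExonGroups, elements: list[GenomicInterval]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fraction of exons per group containing >= 1 bp of merged elements.

    Returns (summary, pairwise) where summary has one row per group
    (n_exons, n_containing, fraction, mean per-bp coverage) and pairwise
    holds Pearson chi-square p-values on containment counts plus KS and
    Wilcoxon rank-sum p-values on the per-exon coverage distributions.
    """
    merged = merge_intervals(elements)
    per_group: dict[str, dict] = {}
    for name, exon_set in groups.as_dict().items():
        overlaps = np.array(
            [overlap_length_with_set(ex, merged) for ex in exon_set], dtype=float
        )
        lengths = np.array([ex.length for ex in exon_set], dtype=float)
        contains = overlaps > 0
        per_group[name] = {
            "n_exons": len(exon_set),
            "n_containing": int(contains.sum()),
            "fraction": float(contains.mean()) if len(exon_set) else float("nan"),
            "coverage": overlaps / lengths if len(exon_set) else np.array([]),
        }
    summary = pd.DataFrame(
        {
            "group": list(per_group),
            "n_exons": [g["n_exons"] for g in per_group.values()],
            "n_containing": [g["n_containing"] for g in per_group.values()],
            "fraction": [g["fraction"] for g in per_group.values()],
            "mean_coverage_per_bp": [
                float(g["coverage"].mean()) if g["n_exons"] else float("nan")
                for g in per_group.values()
            ],
        }
    )
    rows = []
    names = list(per_group)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = per_group[names[i]], per_group[names[j]]
            if a["n_exons"] == 0 or b["n_exons"] == 0:
                rows.append(
                    {"group_a": names[i], "group_b": names[j],
                     "chi2_p": float("nan"), "ks_p": float("nan"),
                     "wilcoxon_p": float("nan")}
                )
                continue
            table = np.array(
                [
                    [a["n_containing"], a["n_exons"] - a["n_containing"]],
                    [b["n_containing"], b["n_exons"] - b["n_containing"]],
                ]
            )
            if (table.sum(axis=0) == 0).any():
                chi2_p = float("nan")
            else:
                chi2_p = float(
                    stats.chi2_contingency(table, correction=False).pvalue
                )
            ks_p = float(stats.ks_2samp(a["coverage"], b["coverage"]).pvalue)
            wil_p = float(
                stats.mannwhitneyu(
                    a["coverage"], b["coverage"], alternative="two-sided"
                ).pvalue
            )
            rows.append(
                {"group_a": names[i], "group_b": names[j],
                 "chi2_p": chi2_p, "ks_p": ks_p, "wilcoxon_p": wil_p}
            )
    return summary, pd.DataFrame(rows)


def sce_observed_vs_expected(
    abundant_circ: dict[str, GenomicInterval],
    circ_coding_exons: dict[str, list[GenomicInterval]],
    sce: list[GenomicInterval],
) -> tuple[pd.DataFrame, EnrichmentExpectation]:
    """Observed vs expected SCE overlap for coding-exon abundant circles.

    The expectation is a uniform per-bp rate over the unique abundant
    circularized coding exons: P_SCE = L_SCE / L_coding_exons and
    expected_i = P_SCE * L_coding_circRNA_i.  Circles without coding
    exons are excluded.
    """
    universe: set[GenomicInterval] = set()
    for cid in abundant_circ:
        universe.update(circ_coding_exons.get(cid, []))
    l_coding = total_length(universe)
    if l_coding == 0:
        raise ValueError("no coding-exon abundant circRNAs: L_coding_exons = 0")
    merged_sce = merge_intervals(sce)
    l_sce = sum(overlap_length_with_set(ex, merged_sce) for ex in universe)
    p_sce = l_sce / l_coding

    rows = []
    for cid in sorted(abundant_circ):
        exons = circ_coding_exons.get(cid, [])
        if not exons:
            continue
        l_cc = total_length(exons)
        observed = sum(overlap_length_with_set(ex, merged_sce) for ex in exons)
        rows.append(
            {
                "circ_id": cid,
                "coding_exon_bp": l_cc,
                "observed_bp": observed,
                "expected_bp": p_sce * l_cc,
            }
        )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["obs_gt_exp"] = table["observed_bp"] > table["expected_bp"]
    return table, EnrichmentExpectation(
        p_sce=p_sce, l_sce=l_sce, l_coding_exons=l_coding
    )


def circ_included_regions(
    circ: GenomicInterval,
    exon_index: IntervalIndex,
    max_len_bp: int = 10_000,
) -> list[GenomicInterval] | None:
    """Genomic regions attributed to a circle for site counting.

    Exonic circles contribute their collapsed clipped exons (introns
    spliced out); non-exonic circles shorter than ``max_len_bp``
    contribute their whole span; longer non-exonic circles are excluded
    (returns None).
    """
    hits = [
        iv for iv, _label in exon_index.overlapping(circ.chrom, circ.start, circ.end)
        if _strand_compatible(iv.strand, circ.strand)
    ]
    if hits:
        spans = merge_spans(
            (max(circ.start, iv.start), min(circ.end, iv.end)) for iv in hits
        )
        return [GenomicInterval(circ.chrom, s, e, circ.strand) for s, e in spans]
    if circ.length < max_len_bp:
        return [circ]
    return None


def mirna_observed_vs_expected(
    abundant_circ: dict[str, GenomicInterval],
    exon_index: IntervalIndex,
    sites: pd.DataFrame,
    max_len_bp: int = 10_000,
    conserved_only: bool = True,
) -> tuple[pd.DataFrame, EnrichmentExpectation]:
    """Observed vs expected (unmerged) miRNA site counts per circle.

    P_miRNA = T_miRNAs / L_exons with totals over the included circles,
    and expected_i = P_miRNA * L_i.  Sites are counted with >= 1 bp
    overlap of the circle's included regions, without merging.
    """
    if conserved_only and "conserved" in sites.columns:
        sites = sites[sites["conserved"].astype(bool)]
    site_ivs = [
        GenomicInterval(r.chrom, r.start, r.end)
        for r in sites.itertuples()
    ]
    site_index = IntervalIndex.build(site_ivs, payloads=list(range(len(site_ivs))))

    rows = []
    for cid in sorted(abundant_circ):
        regions = circ_included_regions(abundant_circ[cid], exon_index, max_len_bp)
        if regions is None:
            continue
        length = total_length(regions)
        hit_ids: set[int] = set()
        for region in regions:
            hit_ids.update(site_index.overlapping(region.chrom, region.start, region.end))
        rows.append({"circ_id": cid, "length_bp": length, "observed_sites": len(hit_ids)})
    table = pd.DataFrame(rows)
    if table.empty:
        return table, EnrichmentExpectation()
    t_mirnas = int(table["observed_sites"].sum())
    l_exons = int(table["length_bp"].sum())
    p_mirna = t_mirnas / l_exons if l_exons else float("nan")
    table["expected_sites"] = p_mirna * table["length_bp"]
    table["obs_gt_exp"] = table["observed_sites"] > table["expected_sites"]
    return table, EnrichmentExpectation(
        p_mirna=p_mirna, t_mirnas=t_mirnas, l_exons=l_exons
    )


def sponge_statistic(
    circ: GenomicInterval, sites: pd.DataFrame, circ_id: str = ""
) -> SpongeStat:
    """Maximal same-miRNA site count within a circle.

    Sites are grouped by (miRNA, experiment); the maximum count and its
    labels are returned, ties broken lexicographically by miRNA id then
    experiment id.  A circle with no sites gets count 0 and empty labels.
    """
    if sites.empty:
        return SpongeStat(circ_id)
    inside = sites[
        (sites["chrom"] == circ.chrom)
        & (sites["start"] < circ.end)
        & (sites["end"] > circ.start)
    ]
    if inside.empty:
        return SpongeStat(circ_id)
    grouped = (
        inside.groupby(["mirna_id", "experiment_id"]).size().reset_index(name="n")
    )
    grouped = grouped.sort_values(
        ["n", "mirna_id", "experiment_id"], ascending=[False, True, True]
    )
    top = grouped.iloc[0]
    return SpongeStat(circ_id, str(top["mirna_id"]), str(top["experiment_id"]), int(top["n"]))
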