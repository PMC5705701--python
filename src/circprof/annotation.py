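"""Genomic and evolutionary annotation of circRNAs and control exons.

Covers: hierarchical genomic-origin classification of splice sites
(CDS > 3'-UTR > 5'-UTR > ncRNA), origin fraction tables with a
chi-square comparison of circular vs linear splicing, collapsed exon
structure of circles, internal-exon control sets, nearest inverted
homologous Alu pair search in 20 kb flanks, and core splice-site
conservation from a per-base score track.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import (
    ConservationTrack,
    GenomicInterval,
    IntervalIndex,
    merge_spans,
)

# priority order: a window overlapping several region classes is assigned
# the highest-priority one
REGION_HIERARCHY = ("CDS", "UTR3", "UTR5", "ncRNA")


@dataclass(frozen=True)
class AluFeature:
    interval: GenomicInterval
    subfamily: str


@dataclass
class AluPairResult:
    """Closest pair of inverted homologous Alus flanking a feature.

    ``distance_bp`` is the sum of the two flank gaps (the span of
    intervening sequence, omitting the feature itself); ``None`` when no
    valid pair exists within the window.
    """

    feature_id: str
    upstream: AluFeature | None
    downstream: AluFeature | None
    distance_bp: int | None


@dataclass
class SpliceConservation:
    """Mean conservation of the four core splice bases of a feature."""

    feature_id: str
    scores: list[float | None]
    mean_score: float
    n_scored: int

    @property
    def defined(self) -> bool:
        return self.n_scored > 0


def build_region_index(exons: pd.DataFrame) -> IntervalIndex:
    """Index exon records as (interval, region label) pairs."""
    ivs = [
        GenomicInterval(r.chrom, r.start, r.end, r.strand)
        for r in exons.itertuples()
    ]
    payloads = list(zip(ivs, exons["region"].tolist()))
    return IntervalIndex.build(ivs, payloads=payloads)


def classify_splice_site(
    chrom: str, position: int, region_index: IntervalIndex, window_bp: int = 6
) -> str:
    """Label of the highest-priority region in a window around a site.

    The window is split symmetrically: [position - w/2, position + w/2).
    Returns "none" when the window overlaps no annotated exon.
    """
    if window_bp % 2:
        raise ValueError("window_bp must be even (split symmetrically)")
    half = window_bp // 2
    start = max(0, position - half)
    hits = region_index.overlapping(chrom, start, position + half)
    labels = {label for _iv, label in hits}
    for label in REGION_HIERARCHY:
        if label in labels:
            return label
    return "none"


def _junction_sites(table: pd.DataFrame) -> pd.DataFrame:
    """Two splice sites (start and end) per unique junction."""
    rows = []
    for r in table.itertuples():
        rows.append((r.chrom, r.start, r.total_reads))
        rows.append((r.chrom, r.end, r.total_reads))
    return pd.DataFrame(rows, columns=["chrom", "position", "reads"])


def origin_fractions(
    circ_table: pd.DataFrame,
    linear_table: pd.DataFrame,
    region_index: IntervalIndex,
    window_bp: int = 6,
) -> tuple[pd.DataFrame, dict]:
    """Genomic-origin fractions of circular vs linear splice sites.

    ``circ_table``/``linear_table`` need columns chrom, start, end,
    total_reads (one row per unique junction).  Returns a table with
    site-count and read-weighted fractions per region label for both
    junction kinds, plus Pearson chi-square comparisons (no continuity
    correction) of the two distributions on the count scale.
    """
    labels = list(REGION_HIERARCHY) + ["none"]
    tallies = {}
    for kind, table in (("circular", circ_table), ("linear", linear_table)):
        sites = _junction_sites(table)
        site_counts = dict.fromkeys(labels, 0)
        read_counts = dict.fromkeys(labels, 0)
        for r in sites.itertuples():
            label = classify_splice_site(r.chrom, r.position, region_index, window_bp)
            site_counts[label] += 1
            read_counts[label] += int(r.reads)
        tallies[kind] = (site_counts, read_counts)

    rows = []
    for label in labels:
        row = {"region": label}
        for kind in ("circular", "linear"):
            sc, rc = tallies[kind]
            n_sites = sum(sc.values()) or 1
            n_reads = sum(rc.values()) or 1
            row[f"{kind}_sites"] = sc[label]
            row[f"{kind}_site_fraction"] = sc[label] / n_sites
            row[f"{kind}_reads"] = rc[label]
            row[f"{kind}_read_fraction"] = rc[label] / n_reads
        rows.append(row)
    fractions = pd.DataFrame(rows)

    tests = {}
    for what, cols in (("sites", ["circular_sites", "linear_sites"]),
                       ("reads", ["circular_reads", "linear_reads"])):
        table2 = fractions[cols].to_numpy()
        keep = table2.sum(axis=1) > 0
        dropped = [l for l, k in zip(fractions["region"], keep) if not k]
        table2 = table2[keep]
        if table2.shape[0] == 1 and (table2 > 0).all():
            # a single shared class: the distributions are identical
            tests[what] = {"statistic": 0.0, "p_value": 1.0,
                           "dropped_classes": dropped}
            continue
        if table2.shape[0] < 2 or (table2.sum(axis=0) == 0).any():
            tests[what] = {"statistic": np.nan, "p_value": np.nan,
                           "dropped_classes": dropped}
            continue
        res = stats.chi2_contingency(table2, correction=False)
        tests[what] = {
            "statistic": float(res.statistic),
            "p_value": float(res.pvalue),
            "dropped_classes": dropped,
        }
    return fractions, tests


def exon_structure(
    circ: GenomicInterval, exon_index: IntervalIndex
) -> tuple[int, int, bool]:
    """Collapsed exon count and exonic length of a circRNA span.

    Exons overlapping the span are clipped to it and unioned (introns
    are assumed spliced out).  A circle overlapping no exon is flagged
    non-exonic and its span length is reported.
    Returns ``(n_exons, exonic_length_bp, is_exonic)``.
    """
    hits = [
        iv for iv, _label in exon_index.overlapping(circ.chrom, circ.start, circ.end)
        if circ.strand == "." or iv.strand == "." or iv.strand == circ.strand
    ]
    if not hits:
        return 0, circ.length, False
    spans = [
        (max(circ.start, iv.start), min(circ.end, iv.end)) for iv in hits
    ]
    merged = merge_spans(spans)
    return len(merged), sum(e - s for s, e in merged), True


def internal_exon_controls(exons: pd.DataFrame) -> list[GenomicInterval]:
    """Internal spliced exons: transcripts with >= 3 exons, first and
    last removed.

    The returned set is deduplicated on (chrom, start, end, strand) and
    ordered lexicographically.
    """
    out: set[GenomicInterval] = set()
    for _tx, grp in exons.groupby("transcript_id"):
        if len(grp) < 3:
            continue
        ordered = grp.sort_values(["start", "end"])
        for r in ordered.iloc[1:-1].itertuples():
            out.add(GenomicInterval(r.chrom, r.start, r.end, r.strand))
    return sorted(out)


def build_alu_index(alu_table: pd.DataFrame) -> IntervalIndex:
    """Index Alu repeats (rows need chrom/start/end/strand/subfamily)."""
    ivs, payloads = [], []
    for r in alu_table.itertuples():
        iv = GenomicInterval(r.chrom, r.start, r.end, r.strand)
        ivs.append(iv)
        payloads.append(AluFeature(iv, r.subfamily))
    return IntervalIndex.build(ivs, payloads=payloads)


def nearest_inverted_alu_pair(
    feature: GenomicInterval,
    alu_index: IntervalIndex,
    window_bp: int = 20_000,
    feature_id: str = "",
) -> AluPairResult:
    """Closest inverted homologous Alu pair flanking a feature.

    Candidate Alus overlap the 20 kb flank by >= 1 bp (they may extend
    beyond it).  A valid pair has equal subfamily class and opposite
    strands, one member per flank.  The distance is
    ``max(0, feature.start - up.end) + max(0, down.start - feature.end)``
    (gaps clamp to zero when an Alu overlaps the feature edge); the
    minimizing pair is returned, ties broken by coordinates.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    up_candidates = [
        a for a in alu_index.overlapping(
            feature.chrom, max(0, feature.start - window_bp), feature.start)
        if a.interval.strand in "+-"
    ]
    down_candidates = [
        a for a in alu_index.overlapping(
            feature.chrom, feature.end, feature.end + window_bp)
        if a.interval.strand in "+-"
    ]
    best: tuple[int, int, int] | None = None
    best_pair: tuple[AluFeature, AluFeature] | None = None
    # group by (subfamily, strand) keeping only the minimal-gap candidate,
    # with coordinate tie-breaks; the scan is then O(#groups^2) at most
    def gap_up(a: AluFeature) -> int:
        return max(0, feature.start - a.interval.end)

    def gap_down(a: AluFeature) -> int:
        return max(0, a.interval.start - feature.end)

    up_best: dict[tuple[str, str], AluFeature] = {}
    for a in up_candidates:
        k = (a.subfamily, a.interval.strand)
        cur = up_best.get(k)
        if cur is None or (gap_up(a), a.interval.start, a.interval.end) < (
            gap_up(cur), cur.interval.start, cur.interval.end
        ):
            up_best[k] = a
    down_best: dict[tuple[str, str], AluFeature] = {}
    for a in down_candidates:
        k = (a.subfamily, a.interval.strand)
        cur = down_best.get(k)
        if cur is None or (gap_down(a), a.interval.start, a.interval.end) < (
            gap_down(cur), cur.interval.start, cur.interval.end
        ):
            down_best[k] = a

    for (sub, strand), up in up_best.items():
        other = "-" if strand == "+" else "+"
        down = down_best.get((sub, other))
        if down is None:
            continue
        dist = gap_up(up) + gap_down(down)
        key = (dist, up.interval.start, down.interval.start)
        if best is None or key < best:
            best = key
            best_pair = (up, down)

    if best_pair is None:
        return AluPairResult(feature_id, None, None, None)
    return AluPairResult(feature_id, best_pair[0], best_pair[1], best[0])


def splice_site_conservation(
    feature: GenomicInterval,
    track: ConservationTrack,
    feature_id: str = "",
    side: str = "intronic",
) -> SpliceConservation:
    """Mean conservation of the four core splice-site bases.

    With ``side="intronic"`` (default) the scored positions are the two
    bases upstream of the feature start and the two bases downstream of
    its end: start-2, start-1, end, end+1 (0-based half-open).  With
    ``side="exonic"`` the terminal feature bases are scored instead.
    Missing positions are skipped; an all-missing feature is flagged
    undefined (``n_scored == 0``, mean NaN).
    """
    if side == "intronic":
        positions = [feature.start - 2, feature.start - 1, feature.end, feature.end + 1]
    elif side == "exonic":
        positions = [feature.start, feature.start + 1, feature.end - 2, feature.end - 1]
    else:
        raise ValueError("side must be 'intronic' or 'exonic'")
    scores = [track.get(feature.chrom, p) if p >= 0 else None for p in positions]
    present = [s for s in scores if s is not None]
    mean = float(np.mean(present)) if present else float("nan")
    return SpliceConservation(feature_id, scores, mean, len(present))
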