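"""End-to-end orchestration: catalog -> annotation -> enrichment ->
class statistics -> survival triage -> combined per-circRNA ledger.

Every stage writes its tables with stable row and column order, so a
fixed configuration (including the seed of the synthetic cohort behind
it) reproduces byte-identical outputs.  Each filter stage logs its
input/output counts to ``run_log.txt`` so catalog numbers are auditable;
the log carries no timestamps for the same reproducibility reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as ann
from . import catalog as cat
from . import enrichment as enr
from . import stats as st
from . import survival as surv
from .intervals import GenomicInterval, IntervalIndex
from .io import (
    AnnotationBundle,
    RunConfig,
    read_annotation_bundle,
    read_clinical_table,
    read_expression_matrix,
    read_junction_table,
)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineResult:
    """In-memory results of a full run (also written as TSVs)."""

    catalog: cat.CircCatalog | None = None
    circ_counts: pd.DataFrame | None = None
    circ_cpm: pd.DataFrame | None = None
    linear_counts: pd.DataFrame | None = None
    ratios: pd.DataFrame | None = None
    abundant_ids: set[str] = field(default_factory=set)
    per_gene: pd.DataFrame | None = None
    origin_fractions: pd.DataFrame | None = None
    origin_tests: dict = field(default_factory=dict)
    exon_structure: pd.DataFrame | None = None
    alu_pairs: pd.DataFrame | None = None
    conservation: pd.DataFrame | None = None
    exon_groups: enr.CodingExonGroups | None = None
    sce_containment: pd.DataFrame | None = None
    sce_containment_tests: pd.DataFrame | None = None
    mirna_containment: pd.DataFrame | None = None
    mirna_containment_tests: pd.DataFrame | None = None
    sce_enrichment: pd.DataFrame | None = None
    mirna_enrichment: pd.DataFrame | None = None
    sponge_stats: pd.DataFrame | None = None
    de_levels: pd.DataFrame | None = None
    de_ratios: pd.DataFrame | None = None
    totals_by_class: pd.DataFrame | None = None
    totals_tests: pd.DataFrame | None = None
    correlations: pd.DataFrame | None = None
    regulator_global: pd.DataFrame | None = None
    eortc: pd.DataFrame | None = None
    triage: pd.DataFrame | None = None
    profiles: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)
    log: list[str] = field(default_factory=list)


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def _circ_to_gene(catalog_table: pd.DataFrame, exons: pd.DataFrame) -> dict[str, str]:
    spans = (
        exons.groupby("gene_id")
        .agg(chrom=("chrom", "first"), start=("start", "min"), end=("end", "max"))
        .reset_index()
        .sort_values(["chrom", "start", "end"])
    )
    index = IntervalIndex.build(
        [GenomicInterval(r.chrom, r.start, r.end) for r in spans.itertuples()],
        payloads=list(spans["gene_id"]),
    )
    mapping = {}
    for r in catalog_table.itertuples():
        genes = index.overlapping(r.chrom, r.start, r.end)
        if genes:
            mapping[r.circ_id] = sorted(genes)[0]
    return mapping


def run_pipeline(config: RunConfig, outdir: str | Path) -> PipelineResult:
    """Run every configured stage and write all output tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res = PipelineResult()

    def log(msg: str) -> None:
        res.log.append(msg)

    def warn(msg: str) -> None:
        res.warnings.append(msg)
        res.log.append(f"WARNING: {msg}")

    # ---------------------------------------------------------- catalog
    try:
        evidence = read_junction_table(config.circ_junctions, kind="circular")
        log(f"catalog: read {len(evidence)} circular junction records")
        filtered = cat.filter_junctions(
            evidence, config.mapq_cutoff, config.allow_missing_mapq
        )
        log(
            f"catalog: MAPQ >= {config.mapq_cutoff:g} on both anchors kept "
            f"{len(filtered)}/{len(evidence)} records"
        )
        clinical = None
        if config.clinical:
            clinical = read_clinical_table(config.clinical)
        sample_ids = (
            sorted(clinical["sample_id"]) if clinical is not None
            else sorted({r.sample_id for r in filtered})
        )
        res.catalog, res.circ_counts = cat.build_catalog(
            filtered, config.min_reads, config.min_samples_robust, sample_ids
        )
        t = res.catalog.table
        log(
            f"catalog: {len(t)} unique backsplices, "
            f"{int(t['detected'].sum())} detected, {int(t['robust'].sum())} robust"
        )
        if clinical is not None:
            libs = clinical.set_index("sample_id")["library_size"]
        else:
            warn("no clinical table: using total backsplice reads as library size")
            libs = res.circ_counts.sum(axis=0).astype(float)
            libs[libs == 0] = 1.0
        res.circ_cpm = cat.cpm_normalize(res.circ_counts, libs)
        res.abundant_ids = cat.flag_abundant(
            res.circ_counts,
            config.abundant_min_samples,
            config.abundant_min_reads,
            expressed_min_reads=config.min_reads,
        )
        log(f"catalog: {len(res.abundant_ids)} abundant circRNAs")

        linear_evidence = []
        if config.linear_junctions:
            linear_evidence = read_junction_table(config.linear_junctions, kind="linear")
            res.linear_counts = cat.linear_counterpart(
                linear_evidence, res.catalog, sample_ids
            )
            res.ratios = cat.circ_to_lin(res.circ_counts, res.linear_counts)
        else:
            warn("no linear junction table: ratio analyses skipped")
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - reported with stage name
        raise StageError(f"catalog stage failed: {exc}") from exc

    # ------------------------------------------------------- annotation
    bundle: AnnotationBundle | None = None
    try:
        if config.exons:
            bundle = read_annotation_bundle(config)
            res.per_gene = cat.per_gene_profile(
                res.circ_counts, res.catalog, bundle.exons
            )
            region_index = ann.build_region_index(bundle.exons)
            robust = res.catalog.table[res.catalog.table["robust"]].copy()
            lin_unique = _linear_junction_table(linear_evidence)
            res.origin_fractions, res.origin_tests = ann.origin_fractions(
                robust, lin_unique, region_index, config.splice_window_bp
            )
            log(
                "annotation: chi-square circular vs linear origin "
                f"p(sites)={res.origin_tests['sites']['p_value']:.3g} "
                f"p(reads)={res.origin_tests['reads']['p_value']:.3g}"
            )

            exon_index = IntervalIndex.build(
                [GenomicInterval(r.chrom, r.start, r.end, r.strand)
                 for r in bundle.exons.itertuples()],
                payloads=[
                    (GenomicInterval(r.chrom, r.start, r.end, r.strand), r.region)
                    for r in bundle.exons.itertuples()
                ],
            )
            struct_rows = []
            for r in robust.itertuples():
                iv = GenomicInterval(r.chrom, r.start, r.end, r.strand)
                n_ex, length, exonic = ann.exon_structure(iv, exon_index)
                struct_rows.append(
                    {"circ_id": r.circ_id, "n_exons": n_ex,
                     "exonic_length_bp": length, "is_exonic": exonic}
                )
            res.exon_structure = pd.DataFrame(struct_rows)

            if bundle.repeats is not None:
                alu_index = ann.build_alu_index(bundle.alu_repeats)
                rows = []
                controls = ann.internal_exon_controls(bundle.exons)
                targets = [
                    ("circRNA", r.circ_id,
                     GenomicInterval(r.chrom, r.start, r.end, r.strand))
                    for r in robust.itertuples()
                ] + [
                    ("internal_exon", f"exon:{iv.chrom}:{iv.start}-{iv.end}", iv)
                    for iv in controls
                ]
                for kind, fid, iv in targets:
                    pair = ann.nearest_inverted_alu_pair(
                        iv, alu_index, config.alu_window_bp, feature_id=fid
                    )
                    rows.append(
                        {"feature_id": fid, "feature_type": kind,
                         "subfamily": pair.upstream.subfamily if pair.upstream else "NA",
                         "distance_bp": pair.distance_bp
                         if pair.distance_bp is not None else np.nan}
                    )
                res.alu_pairs = pd.DataFrame(rows)

            if bundle.conservation is not None:
                rows = []
                for kind, fid, iv in [
                    ("circRNA", r.circ_id,
                     GenomicInterval(r.chrom, r.start, r.end, r.strand))
                    for r in robust.itertuples()
                ] + [
                    ("internal_exon", f"exon:{iv.chrom}:{iv.start}-{iv.end}", iv)
                    for iv in ann.internal_exon_controls(bundle.exons)
                ]:
                    sc = ann.splice_site_conservation(
                        iv, bundle.conservation, feature_id=fid
                    )
                    rows.append(
                        {"feature_id": fid, "feature_type": kind,
                         "mean_score": sc.mean_score, "n_scored": sc.n_scored}
                    )
                res.conservation = pd.DataFrame(rows)
        else:
            warn("no exon annotation: annotation and enrichment stages skipped")
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"annotation stage failed: {exc}") from exc

    # ------------------------------------------------------- enrichment
    try:
        if bundle is not None:
            circ_ivs = res.catalog.intervals("robust")
            abundant_ivs = {
                cid: iv for cid, iv in circ_ivs.items() if cid in res.abundant_ids
            }
            groups, per_circ_exons = enr.build_coding_exon_groups(
                bundle.exons, circ_ivs, res.abundant_ids
            )
            res.exon_groups = groups
            if bundle.sce:
                res.sce_containment, res.sce_containment_tests = (
                    enr.containment_fractions(groups, bundle.sce)
                )
                if abundant_ivs:
                    res.sce_enrichment, _ = enr.sce_observed_vs_expected(
                        abundant_ivs, per_circ_exons, bundle.sce
                    )
            if bundle.mirna_sites is not None:
                sites = bundle.mirna_sites
                conserved = sites[sites["conserved"].astype(bool)]
                site_ivs = [
                    GenomicInterval(r.chrom, r.start, r.end)
                    for r in conserved.itertuples()
                ]
                res.mirna_containment, res.mirna_containment_tests = (
                    enr.containment_fractions(groups, site_ivs)
                )
                exon_index = IntervalIndex.build(
                    [GenomicInterval(r.chrom, r.start, r.end, r.strand)
                     for r in bundle.exons.itertuples()],
                    payloads=[
                        (GenomicInterval(r.chrom, r.start, r.end, r.strand), r.region)
                        for r in bundle.exons.itertuples()
                    ],
                )
                if abundant_ivs:
                    res.mirna_enrichment, _ = enr.mirna_observed_vs_expected(
                        abundant_ivs, exon_index, sites,
                        config.mirna_max_circ_len_bp,
                    )
                    sponge_rows = [
                        enr.sponge_statistic(iv, sites, circ_id=cid)
                        for cid, iv in sorted(abundant_ivs.items())
                    ]
                    res.sponge_stats = pd.DataFrame(
                        [{"circ_id": s.circ_id, "best_mirna": s.best_mirna,
                          "best_experiment": s.best_experiment,
                          "max_same_mirna_sites": s.max_same_mirna_sites}
                         for s in sponge_rows]
                    )
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"enrichment stage failed: {exc}") from exc

    # ------------------------------------------------- class statistics
    gene_expr = None
    try:
        if config.gene_expression:
            gene_expr = read_expression_matrix(config.gene_expression)
        abundant_sorted = sorted(res.abundant_ids)
        ab_cpm = res.circ_cpm.loc[abundant_sorted] if abundant_sorted else None
        if clinical is not None and ab_cpm is not None:
            labels = clinical.set_index("sample_id")["risk_class"]
            res.de_levels = st.wilcoxon_de(
                ab_cpm, labels, 1, 2, config.fdr_level,
                config.log2fc_pseudocount_cpm,
            )
            log(
                f"statistics: {int(res.de_levels['significant'].sum())} of "
                f"{len(res.de_levels)} abundant circRNAs differentially "
                f"expressed (class 1 vs 2)"
            )
            if res.ratios is not None:
                res.de_ratios = st.ratio_de(
                    res.ratios.loc[abundant_sorted], labels, 1, 2, config.fdr_level
                )
            res.totals_by_class, res.totals_tests = st.total_expression_comparison(
                res.circ_cpm, labels
            )
            res.eortc = st.eortc_correlation(
                ab_cpm, clinical.set_index("sample_id")["eortc_score"],
                config.fdr_level,
            )
        elif ab_cpm is None:
            warn("no abundant circRNAs: class statistics skipped")
        else:
            warn("no clinical table: class statistics skipped")
        if gene_expr is not None and ab_cpm is not None:
            res.correlations, res.regulator_global = st.regulator_correlation(
                ab_cpm, gene_expr,
                (config.adar_gene, config.qki_gene), config.fdr_level,
            )
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"statistics stage failed: {exc}") from exc

    # --------------------------------------------------------- survival
    try:
        if clinical is None:
            warn("no clinical table: survival stage skipped")
        elif not res.abundant_ids:
            warn("no abundant circRNAs: survival stage skipped")
        else:
            mapping = (
                _circ_to_gene(res.catalog.table, bundle.exons)
                if bundle is not None else {}
            )
            res.triage = surv.prognostic_triage(
                res.circ_cpm.loc[sorted(res.abundant_ids)],
                res.linear_counts if res.linear_counts is not None
                else res.circ_cpm * 0,
                gene_expr if gene_expr is not None
                else pd.DataFrame(columns=res.circ_cpm.columns),
                clinical,
                mapping,
                config.fdr_level,
            )
            log(
                f"survival: {int(res.triage['independent_prognostic'].sum())} "
                f"circRNAs prognostic independently of linear/mRNA"
            )
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"survival stage failed: {exc}") from exc

    res.profiles = _combined_ledger(res)
    _write_outputs(res, outdir)
    return res


def _linear_junction_table(linear_evidence) -> pd.DataFrame:
    """Unique linear junctions with their total read support."""
    if not linear_evidence:
        return pd.DataFrame(columns=["chrom", "start", "end", "strand", "total_reads"])
    df = pd.DataFrame(
        {
            "chrom": [r.chrom for r in linear_evidence],
            "start": [r.start for r in linear_evidence],
            "end": [r.end for r in linear_evidence],
            "strand": [r.strand for r in linear_evidence],
            "n_reads": [r.n_reads for r in linear_evidence],
        }
    )
    out = (
        df.groupby(["chrom", "start", "end", "strand"], as_index=False)["n_reads"]
        .sum()
        .rename(columns={"n_reads": "total_reads"})
        .sort_values(["chrom", "start", "end", "strand"])
        .reset_index(drop=True)
    )
    return out


def _combined_ledger(res: PipelineResult) -> pd.DataFrame:
    """One row per abundant circRNA with every computed property."""
    if not res.abundant_ids:
        return pd.DataFrame()
    ids = sorted(res.abundant_ids)
    out = pd.DataFrame(index=pd.Index(ids, name="circ_id"))
    t = res.catalog.table.set_index("circ_id")
    out["chrom"] = t.loc[ids, "chrom"]
    out["start"] = t.loc[ids, "start"]
    out["end"] = t.loc[ids, "end"]
    out["strand"] = t.loc[ids, "strand"]
    out["mean_cpm"] = res.circ_cpm.loc[ids].mean(axis=1)
    if res.ratios is not None:
        out["mean_circ_to_lin"] = res.ratios.loc[ids].mean(axis=1)
        out["ratio_gt_1"] = out["mean_circ_to_lin"] > 1
    if res.conservation is not None:
        cons = res.conservation.set_index("feature_id")["mean_score"]
        out["splice_conservation"] = cons.reindex(ids)
    if res.alu_pairs is not None:
        alu = res.alu_pairs.set_index("feature_id")["distance_bp"]
        out["alu_pair_distance_bp"] = alu.reindex(ids)
    for name, table, col in (
        ("sce_obs_gt_exp", res.sce_enrichment, "obs_gt_exp"),
        ("mirna_obs_gt_exp", res.mirna_enrichment, "obs_gt_exp"),
    ):
        if table is not None and not table.empty:
            out[name] = table.set_index("circ_id")[col].reindex(ids)
    if res.sponge_stats is not None and not res.sponge_stats.empty:
        sp = res.sponge_stats.set_index("circ_id")
        out["sponge_mirna"] = sp["best_mirna"].reindex(ids)
        out["sponge_max_sites"] = sp["max_same_mirna_sites"].reindex(ids)
    if res.correlations is not None:
        for partner in res.correlations["partner"].unique():
            sub = res.correlations[res.correlations["partner"] == partner]
            sub = sub.set_index("circ_id")
            out[f"{partner.lower()}_rho"] = sub["spearman_rho"].reindex(ids)
            out[f"{partner.lower()}_significant"] = sub["significant"].reindex(ids)
    if getattr(res, "eortc", None) is not None:
        sub = res.eortc.set_index("circ_id")
        out["eortc_rho"] = sub["spearman_rho"].reindex(ids)
        out["eortc_significant"] = sub["significant"].reindex(ids)
    if res.de_levels is not None:
        out["de_log2fc"] = res.de_levels["log2_fold_change"].reindex(ids)
        out["de_significant"] = res.de_levels["significant"].reindex(ids)
    if res.de_ratios is not None:
        out["ratio_de_significant"] = res.de_ratios["significant"].reindex(ids)
    if res.triage is not None:
        for col in ("q_circ", "q_linear", "q_mrna", "independent_prognostic"):
            out[f"km_{col}" if col.startswith("q") else col] = (
                res.triage[col].reindex(ids)
            )
    return out.reset_index()


def _write_outputs(res: PipelineResult, outdir: Path) -> None:
    if res.catalog is not None:
        _write(res.catalog.table, outdir / "catalog.tsv")
    for name, df, indexed in (
        ("circ_counts", res.circ_counts, True),
        ("circ_cpm", res.circ_cpm, True),
        ("linear_counts", res.linear_counts, True),
        ("ratios", res.ratios, True),
        ("per_gene_profile", res.per_gene, True),
        ("origin_fractions", res.origin_fractions, False),
        ("exon_structure", res.exon_structure, False),
        ("alu_pairs", res.alu_pairs, False),
        ("conservation", res.conservation, False),
        ("sce_containment", res.sce_containment, False),
        ("sce_containment_tests", res.sce_containment_tests, False),
        ("mirna_containment", res.mirna_containment, False),
        ("mirna_containment_tests", res.mirna_containment_tests, False),
        ("sce_enrichment", res.sce_enrichment, False),
        ("mirna_enrichment", res.mirna_enrichment, False),
        ("sponge_stats", res.sponge_stats, False),
        ("de_levels", res.de_levels, True),
        ("de_ratios", res.de_ratios, True),
        ("totals_by_class", res.totals_by_class, False),
        ("totals_tests", res.totals_tests, False),
        ("correlations", res.correlations, False),
        ("regulator_global", res.regulator_global, False),
        ("survival_triage", res.triage, True),
        ("circ_profiles", res.profiles, False),
    ):
        if df is not None:
            _write(df, outdir / f"{name}.tsv", index=indexed)
    with (outdir / "run_log.txt").open("w") as fh:
        for line in res.log:
            fh.write(line + "\n")
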