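"""Synthetic NMIBC-style cohort generator with planted ground truth.

Emulates the structure of a 457-sample early-stage bladder-cancer study:
a small genome with multi-exon genes, backsplice junction counts
(negative binomial with per-sample library-size and class effects),
matching linear splice-junction counts, annotation tracks (inverted
homologous Alu pairs planted in the 20 kb flanks of circRNAs, elevated
conservation at circle core splice sites, SCE and miRNA sites enriched
in abundant-circle exons, one miRNA "sponge" circle), a gene-expression
matrix whose Quaking level tracks global circRNA output, and clinical
outcomes with exponential progression hazards tied to planted prognostic
circRNAs plus independent uniform censoring.

Every random stream derives from ``SimulationDesign.seed``, so a design
maps to byte-identical output files.  Ground truth (which circles are
differentially expressed, prognostic, enriched, Alu-planted, ...) is
returned separately and never consumed by the analysis stages.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .catalog import circ_id as make_circ_id
from .intervals import ConservationTrack, GenomicInterval
from .io import (
    AnnotationBundle,
    JunctionEvidence,
    RunConfig,
    write_bed,
    write_bedgraph,
    write_junction_table,
    write_matrix,
)

_MIRNA_POOL = [f"miR-{k}" for k in (7, 9, 16, 21, 23, 24, 26, 29, 34, 101,
                                    124, 125, 128, 133, 141, 143, 145, 155,
                                    181, 200, 203, 205, 214, 221, 296, 302,
                                    320, 375, 429, 558)]
_EXPERIMENTS = ["brain", "HeLa", "huPancreas", "kidney", "liver",
                "lymphoma", "hESC", "muscle"]
_ALU_CLASSES = ["AluJ", "AluS", "AluY"]


@dataclass
class SimulationDesign:
    """Free parameters of the synthetic cohort.

    Defaults mirror the source study's conditions: 96/232/129 samples in
    risk classes 1/2/3, ~300 circRNAs of which ~40 are abundant,
    negative-binomial counts with dispersion 0.3, a 2-fold class effect
    with 88% of differentially expressed circles down in class 2, a
    ~6.8% progression rate (31/457 in the study) under uniform censoring
    over 60 months, and hazard ratio 3 for the low-expression group of
    each planted prognostic circle.
    """

    # cohort
    n_class1: int = 96
    n_class2: int = 232
    n_class3: int = 129
    # genome
    n_genes: int = 120
    coding_gene_fraction: float = 0.85
    exons_per_gene: tuple[int, int] = (4, 9)
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (800, 2500)
    gene_spacing_bp: int = 50_000
    # circles
    n_circ_target: int = 300
    n_intergenic_circ: int = 6
    n_long_nonexonic_circ: int = 2
    n_abundant_target: int = 40
    abundant_mean_range: tuple[float, float] = (10.0, 40.0)
    background_log_mean: float = -1.0
    background_log_sd: float = 0.8
    dispersion: float = 0.3
    # class effects
    class_activity: tuple[float, float, float] = (1.0, 0.85, 0.7)
    de_fraction_of_abundant: float = 0.4
    de_fold_change: float = 2.0
    fraction_upregulated_in_class2: float = 0.12
    ratio_gt1_fraction: float = 0.15
    # regulators: coupling/noise give a total-expression Spearman rho of
    # roughly 0.3, the magnitude the study reports for Quaking
    qki_effect_sd: float = 0.25
    qki_coupling: float = 0.5
    qki_noise_sd: float = 0.35
    # technical
    library_size_range: tuple[float, float] = (2.0e7, 4.0e7)
    n_decoy_junctions: int = 25
    linear_junction_mean_range: tuple[float, float] = (20.0, 80.0)
    # annotation planting
    alu_planting: float = 0.8
    alu_background_per_bp: float = 1 / 5000
    alu_length: int = 300
    alu_flank_gap: tuple[int, int] = (200, 3000)
    conservation_exon_mean: float = 5.8
    conservation_circ_mean: float = 6.15
    conservation_sd: float = 0.8
    sce_p_enriched: float = 0.6
    sce_p_background: float = 0.08
    sce_cov_enriched: float = 0.35
    sce_cov_background: float = 0.2
    mirna_p_enriched: float = 0.7
    mirna_rate_enriched: float = 1 / 120
    mirna_rate_background: float = 1 / 800
    sponge_sites: int = 8
    # prognosis
    n_prognostic: int = 3
    n_gene_hazard: int = 1
    hazard_ratio: float = 3.0
    class_hazard: tuple[float, float, float] = (1.0, 1.6, 1.3)
    target_event_rate: float = 31 / 457
    censoring_max_months: float = 60.0
    seed: int = 7

    def __post_init__(self) -> None:
        for name in ("alu_planting", "sce_p_enriched", "sce_p_background",
                     "mirna_p_enriched", "de_fraction_of_abundant",
                     "fraction_upregulated_in_class2", "ratio_gt1_fraction",
                     "target_event_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")

    @property
    def n_samples(self) -> int:
        return self.n_class1 + self.n_class2 + self.n_class3


@dataclass
class GroundTruth:
    """Planted per-circRNA and per-sample facts, for validation only."""

    circles: pd.DataFrame
    samples: pd.DataFrame


@dataclass
class _Gene:
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    coding: bool

    @property
    def regions(self) -> list[str]:
        if not self.coding:
            return ["ncRNA"] * len(self.exons)
        labels = ["CDS"] * len(self.exons)
        labels[0], labels[-1] = "UTR5", "UTR3"
        if self.strand == "-":
            labels[0], labels[-1] = "UTR3", "UTR5"
        return labels


@dataclass
class _Circle:
    circ_id: str
    interval: GenomicInterval
    host_gene: str | None
    exon_spans: list[tuple[int, int]]
    abundant: bool = False
    de: bool = False
    de_up_in_class2: bool = False
    prognostic: bool = False
    gene_hazard: bool = False
    sponge: bool = False
    ratio_gt1: bool = False
    alu_planted: bool = False
    sce_enriched: bool = False
    mirna_enriched: bool = False
    baseline_mean: float = 0.0


@dataclass
class _Blueprint:
    genes: list[_Gene]
    circles: list[_Circle]
    chrom_lengths: dict[str, int]


def _rng(design: SimulationDesign, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([design.seed, stream]))


def _build_blueprint(design: SimulationDesign) -> _Blueprint:
    rng = _rng(design, 0)
    genes: list[_Gene] = []
    chrom_cursor = {"chr1": 100_000, "chr2": 100_000}
    for g in range(design.n_genes):
        chrom = "chr1" if g % 2 == 0 else "chr2"
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(design.exons_per_gene[0], design.exons_per_gene[1] + 1))
        pos = chrom_cursor[chrom]
        exons = []
        for i in range(n_ex):
            length = int(rng.integers(design.exon_length[0], design.exon_length[1] + 1))
            exons.append((pos, pos + length))
            pos += length + int(
                rng.integers(design.intron_length[0], design.intron_length[1] + 1)
            )
        coding = bool(rng.random() < design.coding_gene_fraction) and n_ex >= 3
        genes.append(_Gene(f"GENE{g:04d}", chrom, strand, exons, coding))
        chrom_cursor[chrom] += design.gene_spacing_bp

    # exonic circles over runs of internal exons of coding genes
    circles: list[_Circle] = []
    seen: set[tuple] = set()
    eligible = [g for g in genes if g.coding and len(g.exons) >= 4]
    attempts = 0
    while len(circles) < design.n_circ_target and attempts < 50 * design.n_circ_target:
        attempts += 1
        gene = eligible[int(rng.integers(len(eligible)))]
        n_ex = len(gene.exons)
        i = int(rng.integers(1, n_ex - 1))
        j = min(i + int(rng.integers(0, 4)), n_ex - 2)
        start, end = gene.exons[i][0], gene.exons[j][1]
        key = (gene.chrom, start, end, gene.strand)
        if key in seen:
            continue
        seen.add(key)
        circles.append(
            _Circle(
                make_circ_id(*key),
                GenomicInterval(gene.chrom, start, end, gene.strand),
                gene.gene_id,
                gene.exons[i : j + 1],
            )
        )

    # intergenic (non-exonic) circles in a desert at each chromosome end
    desert = {c: chrom_cursor[c] + 100_000 for c in chrom_cursor}
    for k in range(design.n_intergenic_circ + design.n_long_nonexonic_circ):
        chrom = "chr1" if k % 2 == 0 else "chr2"
        start = desert[chrom]
        if k < design.n_intergenic_circ:
            length = int(rng.integers(300, 3000))
        else:
            length = int(rng.integers(12_000, 15_000))
        strand = "+" if rng.random() < 0.5 else "-"
        key = (chrom, start, start + length, strand)
        circles.append(
            _Circle(make_circ_id(*key), GenomicInterval(*key), None, [])
        )
        desert[chrom] += length + 30_000

    chrom_lengths = {c: desert[c] + 100_000 for c in desert}

    # plant flags -------------------------------------------------------
    exonic_idx = [i for i, c in enumerate(circles) if c.host_gene is not None]
    short_intergenic = [
        i for i, c in enumerate(circles)
        if c.host_gene is None and c.interval.length < 10_000
    ]
    n_ab_exonic = max(0, design.n_abundant_target - min(1, len(short_intergenic)))
    abundant_idx = list(
        rng.choice(exonic_idx, size=min(n_ab_exonic, len(exonic_idx)), replace=False)
    )
    sponge_idx = None
    if short_intergenic:
        sponge_idx = short_intergenic[0]
        abundant_idx.append(sponge_idx)
    for i in abundant_idx:
        circles[i].abundant = True
    if sponge_idx is not None:
        circles[sponge_idx].sponge = True

    ab_exonic = [i for i in abundant_idx if circles[i].host_gene is not None]
    n_de = int(round(design.de_fraction_of_abundant * len(abundant_idx)))
    de_idx = list(rng.choice(ab_exonic, size=min(n_de, len(ab_exonic)), replace=False))
    for i in de_idx:
        circles[i].de = True
        circles[i].de_up_in_class2 = bool(
            rng.random() < design.fraction_upregulated_in_class2
        )
    free = [i for i in ab_exonic if not circles[i].de]
    prog_idx = list(rng.choice(free, size=min(design.n_prognostic, len(free)),
                               replace=False))
    for i in prog_idx:
        circles[i].prognostic = True
    free = [i for i in free if not circles[i].prognostic]
    gh_idx = list(rng.choice(free, size=min(design.n_gene_hazard, len(free)),
                             replace=False))
    for i in gh_idx:
        circles[i].gene_hazard = True

    n_ratio = int(round(design.ratio_gt1_fraction * len(circles)))
    ratio_idx = rng.choice(exonic_idx, size=min(n_ratio, len(exonic_idx)), replace=False)
    for i in ratio_idx:
        circles[i].ratio_gt1 = True

    for c in circles:
        c.alu_planted = bool(rng.random() < design.alu_planting)
    for i in abundant_idx:
        circles[i].sce_enriched = bool(rng.random() < design.sce_p_enriched)
        circles[i].mirna_enriched = bool(rng.random() < design.mirna_p_enriched)

    means = rng.uniform(*design.abundant_mean_range, size=len(circles))
    low = np.exp(rng.normal(design.background_log_mean, design.background_log_sd,
                            size=len(circles)))
    for i, c in enumerate(circles):
        c.baseline_mean = float(means[i] if c.abundant else low[i])
    return _Blueprint(genes, circles, chrom_lengths)


# ---------------------------------------------------------------------------
# annotation tracks


def simulate_annotation(design: SimulationDesign) -> AnnotationBundle:
    """Generate the annotation bundle (exons, repeats, conservation,
    SCEs, miRNA sites) with planted structure around the cohort's
    circRNAs."""
    bp = _build_blueprint(design)
    rng = _rng(design, 1)

    exon_rows = []
    for gene in bp.genes:
        labels = gene.regions
        for k, (s, e) in enumerate(gene.exons):
            exon_rows.append(
                {"chrom": gene.chrom, "start": s, "end": e, "strand": gene.strand,
                 "gene_id": gene.gene_id, "transcript_id": f"{gene.gene_id}.t1",
                 "exon_number": k + 1, "region": labels[k]}
            )
    exons = pd.DataFrame(exon_rows)

    # repeats: planted inverted homologous pairs + uniform background
    rep_rows = []
    for c in bp.circles:
        if not c.alu_planted:
            continue
        sub = _ALU_CLASSES[int(rng.integers(3))]
        gap_u = int(rng.integers(*design.alu_flank_gap))
        gap_d = int(rng.integers(*design.alu_flank_gap))
        iv = c.interval
        rep_rows.append(
            {"chrom": iv.chrom, "start": iv.start - gap_u - design.alu_length,
             "end": iv.start - gap_u, "strand": "+", "repeat_name": f"{sub}b"}
        )
        rep_rows.append(
            {"chrom": iv.chrom, "start": iv.end + gap_d,
             "end": iv.end + gap_d + design.alu_length, "strand": "-",
             "repeat_name": f"{sub}b"}
        )
    for chrom, length in bp.chrom_lengths.items():
        n_bg = int(length * design.alu_background_per_bp)
        starts = rng.integers(0, length - design.alu_length, size=n_bg)
        subs = rng.integers(0, 3, size=n_bg)
        strands = rng.integers(0, 2, size=n_bg)
        for s, sub, st in zip(starts, subs, strands):
            rep_rows.append(
                {"chrom": chrom, "start": int(s), "end": int(s) + design.alu_length,
                 "strand": "+" if st else "-",
                 "repeat_name": f"{_ALU_CLASSES[sub]}x"}
            )
        # non-Alu repeats, excluded from the Alu analyses
        for s in rng.integers(0, length - 6000, size=25):
            rep_rows.append(
                {"chrom": chrom, "start": int(s), "end": int(s) + 6000,
                 "strand": "+" if rng.random() < 0.5 else "-",
                 "repeat_name": "L1PA3"}
            )
    repeats = pd.DataFrame(rep_rows)
    repeats["subfamily"] = repeats["repeat_name"].str.extract(r"^(Alu[JSY])")[0]

    # conservation at the four core splice bases of exons and circles
    track = ConservationTrack()
    for gene in bp.genes:
        for s, e in gene.exons:
            for pos in (s - 2, s - 1, e, e + 1):
                track.set_score(
                    gene.chrom, pos,
                    rng.normal(design.conservation_exon_mean, design.conservation_sd),
                )
    for c in bp.circles:
        iv = c.interval
        for pos in (iv.start - 2, iv.start - 1, iv.end, iv.end + 1):
            track.set_score(
                iv.chrom, pos,
                rng.normal(design.conservation_circ_mean, design.conservation_sd),
            )

    # SCEs within coding exons; abundant-circle exons enriched
    enriched_exons: set[tuple[str, int, int]] = set()
    for c in bp.circles:
        if c.sce_enriched or c.mirna_enriched:
            for s, e in c.exon_spans:
                enriched_exons.add((c.interval.chrom, s, e))
    sce_enriched_exons = {
        (c.interval.chrom, s, e)
        for c in bp.circles if c.sce_enriched for s, e in c.exon_spans
    }
    mirna_enriched_exons = {
        (c.interval.chrom, s, e)
        for c in bp.circles if c.mirna_enriched for s, e in c.exon_spans
    }

    sce_ivs: list[GenomicInterval] = []
    mirna_rows = []
    for gene in bp.genes:
        labels = gene.regions
        for (s, e), label in zip(gene.exons, labels):
            if label == "CDS":
                key = (gene.chrom, s, e)
                p_sce = (design.sce_p_enriched if key in sce_enriched_exons
                         else design.sce_p_background)
                cov = (design.sce_cov_enriched if key in sce_enriched_exons
                       else design.sce_cov_background)
                if p_sce > 0 and rng.random() < p_sce:
                    width = max(1, int(cov * (e - s)))
                    off = int(rng.integers(0, e - s - width + 1))
                    sce_ivs.append(GenomicInterval(gene.chrom, s + off, s + off + width))
            rate = (design.mirna_rate_enriched
                    if (gene.chrom, s, e) in mirna_enriched_exons
                    else design.mirna_rate_background)
            n_sites = rng.poisson(rate * (e - s))
            for _ in range(n_sites):
                pos = int(rng.integers(s, max(s + 1, e - 7)))
                mirna_rows.append(
                    {"chrom": gene.chrom, "start": pos, "end": pos + 7,
                     "mirna_id": _MIRNA_POOL[int(rng.integers(len(_MIRNA_POOL)))],
                     "experiment_id": _EXPERIMENTS[int(rng.integers(len(_EXPERIMENTS)))],
                     "conserved": bool(rng.random() < 0.8)}
                )
    # the sponge circle: repeated sites for the same miRNA
    for c in bp.circles:
        if c.sponge:
            iv = c.interval
            for _ in range(design.sponge_sites):
                pos = int(rng.integers(iv.start, iv.end - 7))
                mirna_rows.append(
                    {"chrom": iv.chrom, "start": pos, "end": pos + 7,
                     "mirna_id": "miR-7", "experiment_id": "brain",
                     "conserved": True}
                )
    mirna = pd.DataFrame(
        mirna_rows,
        columns=["chrom", "start", "end", "mirna_id", "experiment_id", "conserved"],
    )
    return AnnotationBundle(
        exons=exons, repeats=repeats, conservation=track,
        sce=sorted(sce_ivs), mirna_sites=mirna,
    )


# ---------------------------------------------------------------------------
# counts


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = m + dispersion * m^2."""
    mean = np.clip(np.asarray(mean, dtype=float), 1e-12, None)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _sample_frame(design: SimulationDesign, rng: np.random.Generator) -> pd.DataFrame:
    n = design.n_samples
    classes = np.repeat([1, 2, 3], [design.n_class1, design.n_class2, design.n_class3])
    return pd.DataFrame(
        {
            "sample_id": [f"S{i:04d}" for i in range(n)],
            "risk_class": classes,
            "library_size": rng.uniform(*design.library_size_range, size=n).round(),
            "activity": np.exp(rng.normal(0.0, design.qki_effect_sd, size=n)),
            "gene_hazard_factor": np.exp(rng.normal(0.0, 0.5, size=n)),
        }
    )


def simulate_counts(
    design: SimulationDesign,
) -> tuple[list[JunctionEvidence], list[JunctionEvidence], pd.DataFrame, GroundTruth]:
    """Backsplice and linear junction evidence, gene expression, truth."""
    bp = _build_blueprint(design)
    rng = _rng(design, 2)
    samples = _sample_frame(design, rng)
    n = len(samples)
    lib_factor = samples["library_size"].to_numpy() / 3e7
    class_factor = np.array(design.class_activity)[samples["risk_class"].to_numpy() - 1]
    activity = samples["activity"].to_numpy()
    gh_factor = samples["gene_hazard_factor"].to_numpy()

    # circular counts --------------------------------------------------
    base = np.array([c.baseline_mean for c in bp.circles])
    mean = base[:, None] * (lib_factor * activity * class_factor)[None, :]
    in_class2 = (samples["risk_class"].to_numpy() == 2)
    for i, c in enumerate(bp.circles):
        if c.de:
            f = design.de_fold_change if c.de_up_in_class2 else 1 / design.de_fold_change
            mean[i, in_class2] *= f
        if c.gene_hazard:
            mean[i] *= gh_factor**2
    circ_counts = _nb_draw(rng, mean, design.dispersion)

    circ_evidence: list[JunctionEvidence] = []
    for i, c in enumerate(bp.circles):
        iv = c.interval
        for j in np.nonzero(circ_counts[i])[0]:
            circ_evidence.append(
                JunctionEvidence(iv.chrom, iv.start, iv.end, iv.strand,
                                 samples["sample_id"].iloc[j],
                                 int(circ_counts[i, j]), 40.0, 40.0)
            )
    # decoy junctions with poor anchor quality (removed by MAPQ filter)
    for _ in range(design.n_decoy_junctions):
        chrom = "chr1" if rng.random() < 0.5 else "chr2"
        s = int(rng.integers(0, bp.chrom_lengths[chrom] - 5000))
        e = s + int(rng.integers(200, 5000))
        for j in rng.choice(n, size=int(rng.integers(1, 4)), replace=False):
            circ_evidence.append(
                JunctionEvidence(chrom, s, e, "+",
                                 samples["sample_id"].iloc[int(j)],
                                 int(rng.integers(2, 10)),
                                 float(rng.integers(10, 31)),
                                 float(rng.integers(10, 31)))
            )

    # linear junction counts -------------------------------------------
    gh_genes = {c.host_gene for c in bp.circles if c.gene_hazard}
    ratio_sites: set[tuple[str, int]] = set()
    for c in bp.circles:
        if c.ratio_gt1:
            ratio_sites.add((c.interval.chrom, c.interval.start))
            ratio_sites.add((c.interval.chrom, c.interval.end))
    linear_evidence: list[JunctionEvidence] = []
    gene_expr_rows = {}
    for gene in bp.genes:
        u = rng.uniform(*design.linear_junction_mean_range)
        gene_factor = gh_factor**2 if gene.gene_id in gh_genes else 1.0
        expr = (
            u * 10 * lib_factor * gene_factor
            * np.exp(rng.normal(0, 0.2, size=n))
        )
        gene_expr_rows[gene.gene_id] = expr
        for (s0, e0), (s1, e1) in zip(gene.exons[:-1], gene.exons[1:]):
            jmean = u * lib_factor * gene_factor
            # circles flagged ratio>1 have (nearly) no linear support at
            # their own splice sites
            if (gene.chrom, e0) in ratio_sites or (gene.chrom, s1) in ratio_sites:
                jmean = jmean * 0.02
            counts = _nb_draw(rng, jmean, design.dispersion)
            for j in np.nonzero(counts)[0]:
                linear_evidence.append(
                    JunctionEvidence(gene.chrom, e0, s1, gene.strand,
                                     samples["sample_id"].iloc[j],
                                     int(counts[j]), 40.0, 40.0)
                )

    # regulators: QKI tracks the global circ activity, ADAR1 does not
    gene_expr_rows["QKI"] = (
        50.0 * activity**design.qki_coupling
        * np.exp(rng.normal(0, design.qki_noise_sd, size=n))
    )
    gene_expr_rows["ADAR1"] = 40.0 * np.exp(rng.normal(0, 0.3, size=n))
    gene_expression = pd.DataFrame(
        gene_expr_rows, index=samples["sample_id"]
    ).T.sort_index()
    gene_expression.index.name = "gene_id"

    # ground truth ------------------------------------------------------
    circ_rows = []
    for i, c in enumerate(bp.circles):
        circ_rows.append(
            {"circ_id": c.circ_id, "host_gene": c.host_gene or "intergenic",
             "baseline_mean": c.baseline_mean,
             "is_abundant_design": c.abundant, "is_de": c.de,
             "de_direction": ("up_class2" if c.de_up_in_class2 else "down_class2")
                             if c.de else "none",
             "is_prognostic": c.prognostic, "is_gene_hazard": c.gene_hazard,
             "is_sponge": c.sponge, "is_ratio_gt1": c.ratio_gt1,
             "alu_planted": c.alu_planted, "is_enriched_sce": c.sce_enriched,
             "is_enriched_mirna": c.mirna_enriched}
        )
    truth_circ = pd.DataFrame(circ_rows)

    # per-sample prognostic groups from the realized CPM (median split)
    cpm = circ_counts / samples["library_size"].to_numpy()[None, :] * 1e6
    n_low = np.zeros(n, dtype=int)
    for i, c in enumerate(bp.circles):
        if c.prognostic:
            med = np.median(cpm[i])
            n_low += (cpm[i] <= med).astype(int)
    gh_low = np.zeros(n, dtype=bool)
    if gh_genes:
        gh_gene = sorted(gh_genes)[0]
        expr = gene_expression.loc[gh_gene].to_numpy()
        gh_low = expr <= np.median(expr)
    truth_samples = samples.copy()
    truth_samples["n_low_prognostic"] = n_low
    truth_samples["gene_hazard_low"] = gh_low
    return circ_evidence, linear_evidence, gene_expression, GroundTruth(
        truth_circ, truth_samples
    )


# ---------------------------------------------------------------------------
# clinical outcomes


def _censored_event_prob(lam: float, c_max: float) -> float:
    """P(exponential event observed before uniform(0, c_max) censoring)."""
    x = lam * c_max
    return 1.0 - (1.0 - np.exp(-x)) / x


def calibrate_base_hazard(
    multipliers: np.ndarray, target_event_rate: float, c_max: float
) -> float:
    """Base hazard such that the cohort's mean event probability matches
    the target, given per-sample hazard multipliers."""

    def f(log_lam: float) -> float:
        lam = np.exp(log_lam)
        return np.mean(
            [_censored_event_prob(lam * m, c_max) for m in multipliers]
        ) - target_event_rate

    return float(np.exp(brentq(f, -20.0, 5.0)))


def simulate_clinical(design: SimulationDesign, truth: GroundTruth) -> pd.DataFrame:
    """Progression times and covariates tied to the planted risk structure.

    Hazard per sample = base * HR^(number of prognostic circles for which
    the sample is in the low-expression group) * HR^(gene-hazard low
    group) * class multiplier; censoring is independent uniform on
    (0, censoring_max_months].  The EORTC score increases monotonically
    in the latent log-hazard.
    """
    rng = _rng(design, 3)
    s = truth.samples
    n = len(s)
    hr = design.hazard_ratio
    mult = (
        hr ** s["n_low_prognostic"].to_numpy()
        * np.where(s["gene_hazard_low"].to_numpy(), hr, 1.0)
        * np.array(design.class_hazard)[s["risk_class"].to_numpy() - 1]
    )
    lam0 = calibrate_base_hazard(mult, design.target_event_rate,
                                 design.censoring_max_months)
    lam = lam0 * mult
    t_event = rng.exponential(1.0 / lam)
    t_cens = rng.uniform(0, design.censoring_max_months, size=n)
    progressed = (t_event <= t_cens).astype(int)
    time = np.maximum(np.minimum(t_event, t_cens), 0.01)

    latent_risk = np.log(lam) + rng.normal(0, 0.3, size=n)
    eortc = np.round(
        (pd.Series(latent_risk).rank(method="first") - 1) / max(1, n - 1) * 23
    ).astype(int)
    stage = np.where(rng.random(n) < 348 / 457, "Ta", "T1")
    grade = np.where(rng.random(n) < 0.6, "low", "high")
    return pd.DataFrame(
        {
            "sample_id": s["sample_id"],
            "risk_class": s["risk_class"],
            "stage": stage,
            "grade": grade,
            "eortc_score": eortc,
            "library_size": s["library_size"].astype(int),
            "time_months": np.round(time, 3),
            "progressed": progressed,
        }
    )


# ---------------------------------------------------------------------------
# one-call cohort writer


def simulate_cohort(
    design: SimulationDesign, outdir: str | Path
) -> tuple[RunConfig, GroundTruth]:
    """Write a complete synthetic study to ``outdir`` and return a
    ready-to-run configuration plus the ground truth.

    Ground-truth tables are written alongside (``truth_*.tsv``) but never
    referenced by the configuration.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = simulate_annotation(design)
    circ_ev, lin_ev, gene_expr, truth = simulate_counts(design)
    clinical = simulate_clinical(design, truth)

    write_junction_table(circ_ev, outdir / "circ_junctions.tsv")
    write_junction_table(lin_ev, outdir / "linear_junctions.tsv")
    bundle.exons.to_csv(outdir / "exons.tsv", sep="\t", index=False)
    bundle.repeats.drop(columns=["subfamily"]).to_csv(
        outdir / "repeats.tsv", sep="\t", index=False
    )
    write_bedgraph(bundle.conservation, outdir / "conservation.bedgraph")
    write_bed(bundle.sce, outdir / "sce.bed")
    bundle.mirna_sites.to_csv(outdir / "mirna_sites.tsv", sep="\t", index=False)
    write_matrix(gene_expr, outdir / "gene_expression.tsv", index_label="gene_id")
    clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
    truth.circles.to_csv(outdir / "truth_circles.tsv", sep="\t", index=False)
    truth.samples.to_csv(outdir / "truth_samples.tsv", sep="\t", index=False)

    config = RunConfig(
        seed=design.seed,
        circ_junctions=str(outdir / "circ_junctions.tsv"),
        linear_junctions=str(outdir / "linear_junctions.tsv"),
        exons=str(outdir / "exons.tsv"),
        repeats=str(outdir / "repeats.tsv"),
        conservation=str(outdir / "conservation.bedgraph"),
        sce=str(outdir / "sce.bed"),
        mirna_sites=str(outdir / "mirna_sites.tsv"),
        gene_expression=str(outdir / "gene_expression.tsv"),
        clinical=str(outdir / "clinical.tsv"),
    )
    config.to_yaml(outdir / "config.yaml")
    return config, truth


# ---------------------------------------------------------------------------
# focused power-study generators


def simulate_de_matrix(
    seed: int,
    n_circ: int = 300,
    n_true: int = 50,
    n_per_class: int = 100,
    fold_change: float = 2.0,
    dispersion: float = 0.3,
    mean_range: tuple[float, float] = (5.0, 50.0),
    fraction_up_in_class2: float = 0.12,
) -> tuple[pd.DataFrame, pd.Series, np.ndarray]:
    """Count matrix with a planted class effect, for power studies.

    The first ``n_true`` circles differ ``fold_change``-fold between
    classes (mostly down in class 2); library sizes are equal so counts
    are CPM-proportional.  Returns (matrix, class labels, truth mask).
    """
    rng = np.random.default_rng(seed)
    base = np.exp(rng.uniform(np.log(mean_range[0]), np.log(mean_range[1]),
                              size=n_circ))
    labels = pd.Series(
        np.repeat([1, 2], n_per_class),
        index=[f"S{i:04d}" for i in range(2 * n_per_class)],
    )
    mean = np.tile(base[:, None], (1, 2 * n_per_class))
    truth = np.zeros(n_circ, dtype=bool)
    truth[:n_true] = True
    up = rng.random(n_true) < fraction_up_in_class2
    factor = np.where(up, fold_change, 1 / fold_change)
    mean[:n_true, n_per_class:] *= factor[:, None]
    counts = _nb_draw(rng, mean, dispersion)
    matrix = pd.DataFrame(counts, columns=labels.index,
                          index=[f"circ{i:04d}" for i in range(n_circ)])
    return matrix, labels, truth


def simulate_triage_cohort(
    seed: int,
    n_samples: int = 300,
    n_circ: int = 40,
    n_prognostic: int = 3,
    n_gene_hazard: int = 1,
    hazard_ratio: float = 3.0,
    target_event_rate: float = 0.1,
    censoring_max_months: float = 60.0,
    dispersion: float = 0.3,
) -> dict:
    """Expression + survival cohort with planted prognostic structure.

    The first ``n_prognostic`` circles carry a circ-specific hazard
    (multiplier ``hazard_ratio`` for the low-expression group, linear
    counterpart and parent gene independent); the next ``n_gene_hazard``
    circles co-vary tightly with their parent gene whose low group
    carries the hazard (so the circle is prognostic but NOT independently
    so).  Returns a dict with circ_cpm, linear_counts, gene_expression,
    clinical, circ_to_gene, and the planted index lists.
    """
    rng = np.random.default_rng(seed)
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    circ_ids = [f"circ{i:03d}" for i in range(n_circ)]
    gene_ids = [f"GENE{i:03d}" for i in range(n_circ)]
    circ_to_gene = dict(zip(circ_ids, gene_ids))

    base = rng.uniform(10, 40, size=n_circ)
    mean = np.tile(base[:, None], (1, n_samples))
    lin_base = rng.uniform(20, 80, size=n_circ)
    lin_mean = np.tile(lin_base[:, None], (1, n_samples))
    gene_expr = np.tile((lin_base * 10)[:, None], (1, n_samples)) * np.exp(
        rng.normal(0, 0.2, size=(n_circ, n_samples))
    )

    gh_idx = list(range(n_prognostic, n_prognostic + n_gene_hazard))
    g_factor = np.exp(rng.normal(0, 0.6, size=n_samples))
    for i in gh_idx:
        mean[i] *= g_factor**2
        lin_mean[i] *= g_factor**2
        gene_expr[i] = lin_base[i] * 10 * g_factor**2 * np.exp(
            rng.normal(0, 0.1, size=n_samples)
        )

    circ_counts = _nb_draw(rng, mean, dispersion)
    linear_counts = _nb_draw(rng, lin_mean, dispersion)

    # hazard multipliers from realized expression groups
    mult = np.ones(n_samples)
    for i in range(n_prognostic):
        low = circ_counts[i] <= np.median(circ_counts[i])
        mult *= np.where(low, hazard_ratio, 1.0)
    for i in gh_idx:
        low = gene_expr[i] <= np.median(gene_expr[i])
        mult *= np.where(low, hazard_ratio, 1.0)
    lam0 = calibrate_base_hazard(mult, target_event_rate, censoring_max_months)
    t_event = rng.exponential(1.0 / (lam0 * mult))
    t_cens = rng.uniform(0, censoring_max_months, size=n_samples)
    progressed = (t_event <= t_cens).astype(int)
    time = np.maximum(np.minimum(t_event, t_cens), 0.01)

    clinical = pd.DataFrame(
        {"sample_id": sample_ids, "risk_class": 1, "stage": "Ta", "grade": "low",
         "eortc_score": 0, "library_size": 30_000_000,
         "time_months": time, "progressed": progressed}
    )
    return {
        "circ_cpm": pd.DataFrame(circ_counts, index=circ_ids, columns=sample_ids),
        "linear_counts": pd.DataFrame(linear_counts, index=circ_ids,
                                      columns=sample_ids),
        "gene_expression": pd.DataFrame(gene_expr, index=gene_ids,
                                        columns=sample_ids),
        "clinical": clinical,
        "circ_to_gene": circ_to_gene,
        "prognostic_idx": list(range(n_prognostic)),
        "gene_hazard_idx": gh_idx,
        "n_events": int(progressed.sum()),
    }
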