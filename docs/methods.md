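# Methods

This note documents the models, conventions and design choices behind
`circprof`, in the order the pipeline runs them.

## Coordinates and identity

All intervals are 0-based half-open internally.  BED-style inputs are
taken as-is; GTF exons (1-based inclusive) are converted on read.  A
circRNA's identity is the `(chrom, start, end, strand)` of its
backsplice junction; strand `.` is allowed and treated as a distinct
key, and minus-strand calls are preserved as given by the upstream
detector rather than coordinate-flipped.

## Catalog

The anchor-quality filter keeps records whose two anchor MAPQs are both
≥ `mapq_cutoff` (default 35, inclusive); records lacking MAPQ fields
pass only when the input is declared pre-filtered.  Tier definitions:

* detected: ≥ `min_reads` (2) backsplice reads in at least one sample;
* robust: ≥ 2 reads in ≥ `min_samples_robust` (2) different samples —
  the working set for every downstream stage;
* abundant: "expressed" (count ≥ the detection threshold of 2 — the
  threshold is not otherwise defined and is exposed as configuration) in
  ≥ 30 samples, with ≥ 20 reads in at least one sample.

CPM uses the per-sample total mapped library size from the clinical
table as denominator, not the backsplice total: library size is a
cohort covariate and the backsplice totals are too small and too
variable to normalize against.  Without a clinical table the pipeline
falls back to backsplice totals and says so in the log.

The linear counterpart of a circle sums linear junction reads ending at
its acceptor plus reads starting at its donor; each site contributes
its own count.  A single physical read serving both sites cannot be
resolved from count tables; treating the two sites additively is an
approximation, documented here.  The circular-to-linear ratio is
`(circ + 1)/(lin + 1)`; the shared pseudocount preserves order, so
ratio > 1 exactly when circular reads exceed linear reads.

## Genomic annotation

Splice-site origin uses a 6 bp window interpreted as ±3 bp around the
junction position, intersected with exon region labels under the fixed
hierarchy CDS > UTR3 > UTR5 > ncRNA (sites overlapping nothing are
"none").  Origin tables are produced both per site and per read
(weighting each site by its junction's total reads); circular and
linear distributions are compared by the Pearson χ² statistic without
continuity correction.  Classes empty in both groups are dropped with a
note; a single shared class yields statistic 0 by convention.

Exon structure collapses (unions) exons overlapping the backsplice
span, clipped to it; the exonic length never exceeds the span length,
and circles touching no exon are flagged non-exonic with the span
length reported.

Internal-exon controls are the exons of ≥ 3-exon transcripts with the
first and last removed — exons whose splicing is unambiguous but which
are not circle boundaries.

### Inverted Alu pairs

Alu subfamily class is the leading `AluJ`/`AluS`/`AluY` prefix of the
RepeatMasker name; other repeats (and bare `Alu` names) are excluded.
A valid pair has equal subfamily class and opposite strands, one member
overlapping each 20 kb flank by ≥ 1 bp (the repeat may extend beyond
the flank).  The reported distance is the sum of the two flank gaps —
the total intervening sequence, omitting the feature itself — with
negative gaps (repeat overlapping the feature edge) clamped to zero.
The alternative reading, min of the two gaps, is not used; the sum
measures the span the paired stems must bridge.  Ties are broken by
coordinates for reproducibility.  The implementation reduces each
(subfamily, strand) group to its minimal-gap candidate per flank, which
is exactly equivalent to the full pair scan (property-tested against
brute force).

### Splice-site conservation

The four scored positions are the two intronic bases on each side of
the backsplice: `start-2, start-1, end, end+1` in half-open
coordinates, i.e. the acceptor AG and donor GT dinucleotide positions.
The wording "two bases upstream and downstream" is directionally
ambiguous; the intronic reading is the default because those are the
bases under splicing constraint, and an `side="exonic"` option scores
the terminal feature bases instead.  Missing track positions are
skipped and the mean is over available scores (an all-missing feature
is flagged undefined rather than zero).  Conservation is averaged per
feature over both sites jointly, not per site then averaged.

## Element enrichment

Coding exons are collapsed exons with ≥ 90% of their bases in CDS
annotation (boundary inclusive).  "Circularized" means 100% containment
of the exon within the circle's genomic span — internal splicing
structure is unobserved, so containment in the span is the operational
definition.  Exons are assigned hierarchically: abundant-circle exons
take precedence over non-abundant-circle exons over linear-only; the
three groups partition the coding exons (asserted at run time).

Containment fractions use *merged* element intervals (overlapping
sites unioned) and ≥ 1 bp overlap; group pairs are compared by Pearson
χ² on containment counts and by KS and Wilcoxon rank-sum on the
per-exon coverage (overlap/exon length) distributions.

Observed-vs-expected controls for exon size with a uniform per-bp
rate.  For SCEs the universe is the unique abundant circularized coding
exons: `P_SCE = L_SCE / L_coding_exons` and
`E_i = P_SCE × L_coding_circRNA,i`; circles without coding exons are
excluded.  For miRNA sites the included circles are exonic circles
(length = collapsed exonic length, introns spliced out) plus non-exonic
circles shorter than 10 kb; `P_miRNA = T / L` with totals over included
circles.  Observed miRNA counts use *unmerged* sites (a count, not a
length), without deduplication across experiments — the alternative
(deduplicated) reading would only lower both observed and expected
totals together.  On a fixture where every base belongs to exactly one
circle, total expected equals total observed for both element types;
this identity is tested to 1e-9 relative error.

The sponge statistic counts sites per (miRNA, experiment) within the
circle's span and reports the maximum; ties break lexicographically.
The conserved-miRNA restriction is an input-table flag, not a
computation.

## Class statistics

Differential expression uses the two-sided Wilcoxon rank-sum test on
CPM rows, class 1 vs class 2 (class 3 is biologically heterogeneous and
excluded by default; pairwise mode exists).  CPM rather than raw counts
is the default because the rank test is library-size sensitive; the raw
scale can be passed explicitly.  The exact null distribution is used
when the smaller group has ≤ 8 samples and the pooled data has no ties;
otherwise the normal approximation with tie and continuity correction —
the branch is deterministic, so p-values are bit-reproducible.
`log2FC = log2((mean1 + ε)/(mean2 + ε))` with ε = 1 CPM (configurable);
the sign convention is positive = higher in class 1.  Ratio-scale DE
applies the same test to the circ-to-lin ratio rows (no pseudocount in
the fold change; ratios are already strictly positive).

BH adjustment is the standard step-up procedure (via statsmodels),
applied within one family per analysis — DE levels, DE ratios, each
correlation partner, each survival measurement family — mirroring
per-figure correction rather than a single global family.  NaN p-values
(degenerate inputs) are excluded from their family and preserved.

## Survival triage

Median split: high = strictly greater than the median.  Ties go to the
low group deliberately: circRNA expression is heavily zero-inflated, and
this rule puts all-zero samples together instead of splitting them
arbitrarily.  A constant vector yields a degenerate split, excluded
from its family's BH with a note.

The log-rank statistic is the classical two-group form: at each event
time, observed minus hypergeometric expected events in one group,
variance `d·(n1/n)(1−n1/n)(n−d)/(n−1)`, summed and squared over the
variance; p from χ² with 1 df.  No events or zero variance returns NaN
(degenerate input).  The Kaplan–Meier estimator is the product-limit
form with censorings at an event time still counted at risk at that
time.  Both are validated against hand-computed tables and lifelines.

A circle is independently prognostic when its own q < FDR level while
its linear counterpart's and parent gene's are not (degenerate or
missing partners count as non-significant — a partner that cannot be
tested cannot explain the signal).  The event is progression to
muscle-invasive disease (T2+); no multivariate adjustment and no
optimal-cutoff search is attempted — the median is a pre-registered,
if suboptimal, threshold.

## Synthetic cohort

The generator emulates the structure of a 457-sample early-stage
bladder-cancer study; its defaults are the study's conditions, and all
streams derive from one seed (byte-identical outputs per design).

* **Cohort**: 96/232/129 samples in risk classes 1/2/3; library sizes
  uniform on 20–40 M; stage mix ~76% Ta.
* **Genome**: 120 genes on two chromosomes, 4–9 exons of 80–300 bp,
  introns 0.8–2.5 kb, 50 kb gene spacing; coding genes get
  UTR5/CDS/UTR3 labels, ~15% are ncRNA.  ~300 circles span runs of
  internal exons; a few intergenic circles (including two > 10 kb, which
  the miRNA analysis must exclude) live in gene deserts.
* **Counts**: negative binomial with `var = m + 0.3 m²`.  Zero-inflation
  seen in real cohorts is reproduced through low means rather than a
  separate inflation parameter, keeping the model minimal.  ~40
  abundant-destined circles have means 10–40; background circles have
  log-normal means around e⁻¹.  Per-sample factors: library size, a
  latent circularization activity (log-sd 0.25) shared by all circles,
  and class activity 1.0/0.85/0.7 (total circ expression decreasing
  class 1 → 3).
* **Class effect**: 40% of abundant circles are DE with fold 2, 88% of
  them down in class 2.  The source study gives no quantitative
  fold-change distribution; fold 2 is a moderate, detectable effect and
  is a free parameter of the design.
* **Regulators**: QKI expression is a noisy power of the latent
  activity, tuned to a total-expression Spearman ρ of roughly 0.3 — the
  magnitude reported for Quaking in the emulated study; ADAR1 is
  independent.
* **Annotation planting**: each circle gets an inverted homologous Alu
  pair in its 20 kb flanks with probability 0.8 (gaps 0.2–3 kb) over a
  uniform background of one Alu per 5 kb; conservation at circle splice
  bases is N(6.15, 0.8) vs N(5.8, 0.8) at exon boundaries (the values
  the emulated study reports for circles and exons); SCEs cover ~35% of
  an enriched exon with probability 0.6 (background 0.2 @ 0.08); miRNA
  sites are Poisson at 1/120 bp in enriched exons vs 1/800 bp
  background; one intergenic "sponge" circle carries 8 same-miRNA
  sites (miR-7, brain), mirroring the known extreme case.
* **Clinical**: per-sample hazard = base × HR^(number of prognostic
  circles whose low-expression group the sample is in) × HR^(gene-level
  hazard group) × class multiplier (1/1.6/1.3); HR = 3.  The base
  hazard is solved numerically so the mean event probability under
  uniform censoring on (0, 60] months equals the target rate (default
  31/457 ≈ 6.8%).  Hazard ties to the *median-split group* of each
  prognostic circle, not its continuous value, so the triage target is
  well-defined.  EORTC scores are a rank transform of the latent
  log-hazard (0–23), hence monotone in true risk.

What the generator does **not** emulate: read-level sequence content,
alignment artifacts, batch structure, isoform-resolved circle interiors,
mutations, and correlated miRNA/SCE placement beyond per-exon rates.
Passing tests therefore demonstrate correctness of the statistical
machinery and recoverability of planted effects under NB noise — not
robustness to alignment or batch pathologies of real data.

Two focused helpers, `simulate_de_matrix` and `simulate_triage_cohort`,
plant single effects (a 2-fold class shift; circ-specific and
gene-level hazards) without the annotation machinery, for power and
type-I studies at scale.

## Problem sizes and numerical conventions

The validation suite runs the full pipeline at study scale (457
samples, ~300 circles; seconds per run), differential-expression
recovery at 300 circles × 200 samples × 20 seeds, triage recovery at
300 samples (~30 events) × 40 circles × 20 seeds, and null simulations
at 200 replicates — sizes at which the asymptotic tests are trustworthy
and Monte-Carlo rates are stable.  With ~30 events and a 40-test BH
family, the per-circle power of the triage at HR 3 is about 0.5; three
planted circles (the 13/279 proportion of the emulated study, scaled)
give a high probability that the analysis recovers the planted effect
per run, which is what the recovery checks assert.

Output tables are written with stable row/column order and `%.6g`
floats; the run log carries no timestamps; given one configuration the
pipeline is byte-identical across runs.  Degenerate cases are flagged
rather than silently dropped: constant DE rows (p = 1), constant
correlation partners (NaN, excluded from BH), degenerate median splits,
all-missing conservation.
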