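# circprof

Circular RNAs (circRNAs) are covalently closed transcripts formed when a
downstream splice donor "backsplices" to an upstream acceptor.  In tumor
transcriptomes they are detectable as reads spanning the out-of-order
junction, and a handful of them carry prognostic information that the
host gene's linear transcript does not.  `circprof` is a library for the
downstream half of that analysis: it consumes per-sample backsplice
junction candidates (as produced by detectors such as find_circ), builds
and filters a circRNA catalog, characterizes the circles genomically and
evolutionarily, tests for class-wise differential expression, and
triages candidates whose expression predicts progression independently
of their linear counterparts.  It is aimed at computational biologists
working with bulk RNA-seq cohorts of early-stage cancers, and it ships a
full synthetic-cohort generator with planted ground truth so every stage
can be validated end to end.

## What it computes

* **Catalog** — a circRNA is keyed by its backsplice junction
  `(chrom, start, end, strand)`.  Records with either anchor MAPQ < 35
  are discarded.  Tiers: *detected* (≥ 2 reads in one sample), *robust*
  (≥ 2 reads in ≥ 2 samples; the working set), *abundant* (expressed in
  ≥ 30 samples and ≥ 20 reads in at least one).  Counts are normalized
  to CPM against per-sample library size, and the per-sample
  circular-to-linear ratio is

  `r = (n_circ + 1) / (n_lin + 1)`,

  where `n_lin` sums the linear junction reads using the circle's own
  donor and acceptor sites (the pseudocount avoids division by zero, and
  `r > 1` iff circular reads outnumber linear ones).
* **Genomic annotation** — splice sites are assigned a genomic origin by
  intersecting a 6 bp window with exon annotation under the hierarchy
  CDS > 3′-UTR > 5′-UTR > ncRNA; circular vs linear origin distributions
  are compared with a Pearson χ² test.  Exon structure is the collapsed
  union of exons clipped to the backsplice span (introns assumed spliced
  out).
* **Alu pairing** — for each circle (and each internal exon as control),
  the nearest pair of *inverted homologous* Alu repeats (same subfamily
  class AluJ/AluS/AluY, opposite strands, one per 20 kb flank) is found;
  the distance is the sum of the two flank gaps.
* **Conservation** — the mean per-base conservation (PhyloP-style track)
  of the four core splice nucleotides: two bases upstream of the
  acceptor and two downstream of the donor.
* **Element enrichment** — collapsed coding exons (≥ 90% CDS bases) are
  hierarchically grouped (inside abundant circles > non-abundant >
  linear-only); containment fractions of synonymous constraint elements
  (SCEs) and AGO-CLIP miRNA target sites are compared across groups, and
  per-circle observed overlap is contrasted with the expectation
  `E_i = (L_elements / L_total) × L_i` controlling for exon size.  The
  sponge statistic is the maximal same-miRNA site count within a circle.
* **Differential expression** — two-sided Wilcoxon rank-sum tests on CPM
  (and on circ-to-lin ratios) between risk classes 1 and 2, with
  Benjamini–Hochberg control at FDR < 0.1; `log2FC > 0` means higher in
  class 1.  Spearman correlations against ADAR1, QKI (Quaking), and the
  EORTC clinical score use the same FDR machinery.
* **Prognostic triage** — patients are median-split on each abundant
  circle's CPM (ties to the low group) and progression-free survival is
  compared by the two-group log-rank test (hypergeometric
  expectation/variance, χ² with 1 df; Kaplan–Meier product-limit curves
  available).  The same test is run on the linear counterpart and the
  parent gene's mRNA; a circle is *independently prognostic* when
  `q_circ < 0.1` while neither `q_linear` nor `q_mrna` is significant.

## Worked example

`examples/` contains one narrative script per capability.  The survival
triage on a synthetic study-scale cohort (457 patients, seed 42):

```bash
python examples/06_prognostic_triage.py
```

```
cohort: 457 patients, 31 progressed to T2+
abundant circRNAs triaged: 40
log-rank q < 0.1 on circ expression:  3
independently prognostic (circ significant, linear and mRNA not): 3

candidates:
                         q_circ  q_linear  q_mrna
circ_id
chr1:1652362-1657069(+)  0.0650    0.8362  0.9487
chr2:104643-104811(+)    0.0669    0.5345  0.9487
chr2:651740-656628(+)    0.0633    0.8362  0.9487

planted prognostic circles recovered: 3/3
```

Each candidate's circular expression separates progressors from
non-progressors (BH-corrected log-rank q < 0.1) while its linear
transcript and host mRNA do not — the survival signal lives in the
circular isoform.  Here all three circles the generator planted with a
circ-specific hazard are recovered and nothing else is flagged.

The whole pipeline is also available as a thin CLI:

```bash
circprof simulate --seed 7 --outdir cohort/
circprof all --config cohort/config.yaml --outdir results/
```

which writes per-stage tables plus `circ_profiles.tsv`, a combined
per-circRNA ledger of every computed property.

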