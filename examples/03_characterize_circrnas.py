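"""Characterize circRNAs: genomic origin, inverted Alu pairs, splice-site
conservation — contrasted with internal (non-circularized) exons.
"""

from pathlib import Path

from circprof import RunConfig, SimulationDesign, run_pipeline, simulate_cohort

cohort = Path("scratch/example_cohort")
if not (cohort / "config.yaml").exists():
    simulate_cohort(SimulationDesign(n_class1=30, n_class2=60, n_class3=30,
                                     n_circ_target=120, n_abundant_target=20,
                                     seed=42), cohort)
config = RunConfig.from_yaml(cohort / "config.yaml")
res = run_pipeline(config, Path("scratch/example_out"))

fr = res.origin_fractions.set_index("region")
print("splice-site genomic origin (fraction of sites):")
for region in ("CDS", "UTR3", "UTR5", "ncRNA", "none"):
    print(f"  {region:<6} circular {fr.loc[region, 'circular_site_fraction']:.3f}"
          f"  linear {fr.loc[region, 'linear_site_fraction']:.3f}")
print(f"chi-square circular vs linear: "
      f"p = {res.origin_tests['sites']['p_value']:.3g}")

alu = res.alu_pairs
circ_d = alu.loc[alu.feature_type == "circRNA", "distance_bp"].dropna()
exon_d = alu.loc[alu.feature_type == "internal_exon", "distance_bp"].dropna()
print(f"\nnearest inverted homologous Alu pair (median distance, bp):")
print(f"  circRNAs:       {circ_d.median():.0f}   (n={len(circ_d)})")
print(f"  internal exons: {exon_d.median():.0f}   (n={len(exon_d)})")

cons = res.conservation
circ_c = cons.loc[cons.feature_type == "circRNA", "mean_score"].dropna()
exon_c = cons.loc[cons.feature_type == "internal_exon", "mean_score"].dropna()
print(f"\ncore splice-site conservation (mean of 4 bases):")
print(f"  circRNAs:       {circ_c.mean():.2f}")
print(f"  internal exons: {exon_c.mean():.2f}")
# Shorter Alu distances and higher conservation at circle splice sites
# are the signatures of intron-pairing-driven, evolutionarily maintained
# backsplicing.
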