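"""Generate a synthetic bladder-cancer-style cohort with known truth.

Writes junction tables, annotation tracks, gene expression and clinical
outcomes for a scaled-down cohort, then prints what was planted.
"""

from pathlib import Path

from circprof import SimulationDesign, simulate_cohort

design = SimulationDesign(
    n_class1=30, n_class2=60, n_class3=30,   # three tumor risk classes
    n_circ_target=120, n_abundant_target=20,
    seed=42,
)
outdir = Path("scratch/example_cohort")
config, truth = simulate_cohort(design, outdir)

t = truth.circles
print(f"cohort written to {outdir}/ ({design.n_samples} samples)")
print(f"circRNAs simulated:        {len(t)}")
print(f"  abundant by design:      {int(t.is_abundant_design.sum())}")
print(f"  differentially expressed:{int(t.is_de.sum()):>4}  "
      f"({(t.de_direction == 'down_class2').sum()} down in class 2)")
print(f"  prognostic (circ-only):  {int(t.is_prognostic.sum())}")
print(f"  Alu pair planted:        {int(t.alu_planted.sum())}")
print(f"  miRNA sponge circle:     {int(t.is_sponge.sum())}")
# These flags are the ground truth that the analysis stages (examples
# 02-06) are expected to recover from the written tables alone.
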