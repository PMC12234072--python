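"""Simulate a WGBS study with planted DMRs and inspect the ground truth.

Builds a toy genome of clustered CpG dyads, plants differentially
methylated regions, and draws per-sample counts at ~15x coverage with a
bimodal baseline targeting the ~67% global methylation typical of a
vertebrate liver methylome.
"""

import numpy as np

from pacmeth import generate_genome_layout, generate_methylomes, plant_dmrs

maps = generate_genome_layout(n_chrom=2, chrom_length=400_000, n_cpg=1500, seed=1)
dmrs = plant_dmrs(maps, n_dmr=20, mean_length=400, delta=0.25, hyper_fraction=0.1, seed=2)
tables, sheet = generate_methylomes(maps, dmrs, n_per_group=(8, 8), seed=3)

meth = sum(t.data["n_meth"].sum() for t in tables)
total = sum(t.data["n_total"].sum() for t in tables)
print(f"samples: {len(tables)} ({sheet['group'].value_counts().to_dict()})")
print(f"CpG dyads per sample: ~{len(tables[0])}")
print(f"global methylation fraction: {meth / total:.3f}  (target 0.67)")
print(f"mean coverage: {np.mean([t.data['n_total'].mean() for t in tables]):.1f}x (target 15x)")
n_hyper = sum(d.delta > 0 for d in dmrs)
print(f"planted DMRs: {len(dmrs)} ({n_hyper} hyper, {len(dmrs) - n_hyper} hypo), "
      f"mean length {np.mean([d.length for d in dmrs]):.0f} bp")
# The global methylation fraction and coverage should sit near their
# targets; planted DMRs are the ground truth recovered in example 02.
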