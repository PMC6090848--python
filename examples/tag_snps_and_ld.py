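"""Quantify linkage disequilibrium and pick tag SNPs.

Shows the haplotype LD measures (D, D', r^2) on a worked 2x2 haplotype
count table, then selects tag SNPs on a simulated high-LD chromosome:
greedy maximal coverage at r^2 >= 0.99 within a 100 kb window, MAF > 0.05.
"""

import numpy as np

from equiqtl import SimConfig, haplotype_ld, select_tag_snps, simulate_genotypes

# haplotype counts AB/Ab/aB/ab = 40/10/10/40 across 100 haplotypes
a = np.array([1] * 50 + [0] * 50)
b = np.array([1] * 40 + [0] * 10 + [1] * 10 + [0] * 40)
ld = haplotype_ld(a, b)
print(f"worked example: D = {ld.D:.2f}, D' = {ld.Dprime:.2f}, "
      f"r^2 = {ld.r2:.2f}")

cfg = SimConfig(seed=17, n_chroms=1, n_snps=500, ld_decay=0.95,
                chrom_length_bp=10_000_000)
genos = simulate_genotypes(cfg)
tags = select_tag_snps(genos, window_bp=100_000, r2_threshold=0.99,
                       maf_min=0.05)
eligible = sum(s.maf > 0.05 for s in genos.snps)
sizes = sorted((len(v) for v in tags.represented.values()), reverse=True)
print(f"{eligible} SNPs above the MAF floor -> {len(tags.tags)} tags")
print(f"largest blocks covered by one tag: {sizes[:5]}")
print("every non-tag SNP has r^2 >= 0.99 with its tag within 100 kb, so "
      "testing tags alone loses almost no association signal.")
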