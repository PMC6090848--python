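"""Simulate the study cohort and inspect its genetic structure.

Builds 82 individuals (two half-sib families of 17 and 15 plus 50
unrelated), phased SNPs with tunable LD, and prints the structure a real
cohort of this design would show: adjacent-site LD, and higher genotype
correlation within a half-sib family than between unrelated animals.
"""

import itertools

import numpy as np

from equiqtl import SimConfig, simulate_genotypes

cfg = SimConfig(seed=7, n_chroms=2, n_snps=200, ld_decay=0.9)
genos = simulate_genotypes(cfg)
print(f"cohort: {genos.n_samples} individuals x {genos.n_snps} phased SNPs")

haps = genos.haplotypes.transpose(0, 2, 1).reshape(-1, genos.n_snps).astype(float)
r2 = [
    np.corrcoef(haps[:, j], haps[:, j + 1])[0, 1] ** 2
    for j in range(199)
    if haps[:, j].std() > 0 and haps[:, j + 1].std() > 0
]
print(f"mean adjacent-site haplotype r^2: {np.mean(r2):.3f} "
      f"(copying probability {cfg.ld_decay})")

corr = np.corrcoef(genos.dosage)
fam1 = range(50, 67)
unrel = range(50)
within = np.mean([corr[i, j] for i, j in itertools.combinations(fam1, 2)])
between = np.mean([corr[i, j] for i, j in itertools.combinations(unrel, 2)])
print(f"mean genotype correlation within Fam1: {within:.3f}; "
      f"between unrelated: {between:.3f}")
print("half-sibs share one recombinant sire haplotype, hence the excess.")
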