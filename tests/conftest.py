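import numpy as np
import pytest

from equiqtl import SimConfig, simulate_expression, simulate_gene_models, simulate_genotypes


def write_vcf(path, records, samples, phased=False):
    """Write a minimal VCF 4.2 file.

    ``records``: list of (chrom, pos, vid, ref, alt_field, genotype_strings).
    """
    sep = "|" if phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in sorted({r[0] for r in records}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for chrom, pos, vid, ref, alt, gts in records:
            gt_strs = []
            for g in gts:
                if g is None:
                    gt_strs.append(f".{sep}.")
                elif g == 0:
                    gt_strs.append(f"0{sep}0")
                elif g == 1:
                    gt_strs.append(f"0{sep}1")
                else:
                    gt_strs.append(f"1{sep}1")
            fh.write(
                f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gt_strs)
                + "\n"
            )
    return str(path)


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort with genotypes, gene models, counts and truth."""
    cfg = SimConfig(
        seed=11,
        n_unrelated=30,
        n_fam1=10,
        n_fam2=10,
        n_chroms=2,
        n_snps=120,
        n_genes=80,
        n_noise_genes=20,
        ld_decay=0.8,
    )
    genos = simulate_genotypes(cfg)
    genes = simulate_gene_models(genos, cfg)
    counts, truth = simulate_expression(genos, cfg)
    return cfg, genos, genes, counts, truth


def ols_oracle(y, g):
    """Textbook simple-regression slope, t and p for y ~ 1 + g."""
    import scipy.stats as st

    n = len(y)
    gc = g - np.mean(g)
    yc = y - np.mean(y)
    slope = float(gc @ yc / (gc @ gc))
    resid = yc - slope * gc
    se = np.sqrt(float(resid @ resid) / (n - 2) / float(gc @ gc))
    t = slope / se
    p = 2 * st.t.sf(abs(t), n - 2)
    return slope, t, p
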