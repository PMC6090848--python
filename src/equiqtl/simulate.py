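"""Synthetic cohort generator with planted ground truth.

Emulates the data layout of a family-structured eQTL study: 82 individuals
(two half-sib families of 17 and 15 offspring plus 50 unrelated), phased
SNPs with tunable linkage disequilibrium, negative-binomial RNA-seq counts
with planted additive cis effects, one optional trans-regulatory hotspot,
latent batch factors, low-expression "noise" genes, single-sample outlier
spikes, and a binary disease phenotype partially driven by a few SNPs.

Haplotypes follow a first-order Markov copying chain along each
chromosome: with probability ``ld_decay`` a site copies the previous
site's allele, otherwise it draws a fresh Bernoulli at the site's own
allele frequency.  Adjacent-site haplotype correlation is therefore about
``ld_decay`` (r^2 about its square), giving a single tunable tagging
knob.  Half-sib offspring inherit one recombinant sire haplotype (a
single uniform crossover per chromosome per meiosis) and one fresh
founder haplotype.

Everything is deterministic under ``SimConfig.seed``; independent substreams
keep the three generators reproducible regardless of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .io_formats import CountMatrix, GeneModel, GenotypeMatrix, SnpRecord

import pandas as pd


@dataclass
class SimConfig:
    """Knobs for the synthetic cohort; defaults are the study conditions."""

    n_unrelated: int = 50
    n_fam1: int = 17
    n_fam2: int = 15
    n_chroms: int = 4
    n_snps: int = 250  # per chromosome
    chrom_length_bp: int = 50_000_000
    ld_decay: float = 0.9  # latent AR(1) autocorrelation between adjacent SNPs
    maf_low: float = 0.05
    maf_high: float = 0.5
    n_genes: int = 300
    n_noise_genes: int = 100
    noise_mean_max: float = 5.0  # ceiling for noise-gene mean counts
    noise_shift_sd: float = 0.3  # per-sample log-scale distortion of noise genes
    nb_dispersion: float = 0.1
    cis_effects: list[tuple[str, str, float]] = field(default_factory=list)
    cis_tss_sd: float = 50_000.0  # TSS offset SD for planted cis genes
    hotspot: tuple[str, int, float] | None = None  # (snp, n targets, fold change)
    n_batch_factors: int = 0
    batch_loading_sd: float = 0.3
    batch_affected_frac: float = 0.5
    outliers: list[tuple[str, str, float]] = field(default_factory=list)
    pheno_snps: list[tuple[str, float]] = field(default_factory=list)
    pheno_intercept: float = 0.0
    fam1_offset: float = 0.75
    fam2_offset: float = 0.75
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("SimConfig.seed is mandatory")
        if min(self.n_unrelated, self.n_fam1, self.n_fam2) < 0:
            raise ValueError("cohort sizes must be >= 0")
        if any(fc <= 0 for _, _, fc in self.cis_effects):
            raise ValueError("fold changes must be > 0")

    @property
    def n_samples(self) -> int:
        return self.n_unrelated + self.n_fam1 + self.n_fam2

    def sample_ids(self) -> list[str]:
        return (
            [f"U{i:03d}" for i in range(self.n_unrelated)]
            + [f"F1_{i:03d}" for i in range(self.n_fam1)]
            + [f"F2_{i:03d}" for i in range(self.n_fam2)]
        )

    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)] + [
            f"NG{i:04d}" for i in range(self.n_noise_genes)
        ]


@dataclass
class TruthSet:
    """Planted ground truth for parameter-recovery tests."""

    cis_pairs: list[tuple[str, str, float]]
    hotspot_snp: str | None
    hotspot_genes: list[str]
    outliers: list[tuple[str, str, float]]
    pheno_snps: list[tuple[str, float]]
    noise_genes: list[str]
    batch_scores: np.ndarray | None = None  # k x samples


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _draw_haplotype(
    rng: np.random.Generator, freqs: np.ndarray, copy_prob: float
) -> np.ndarray:
    """One haplotype from the first-order allele-copying chain."""
    m = freqs.size
    fresh = (rng.random(m) < freqs).astype(np.int8)
    if copy_prob <= 0:
        return fresh
    copied = np.empty(m, dtype=bool)
    copied[0] = False
    copied[1:] = rng.random(m - 1) < copy_prob
    # each site takes the fresh draw at the most recent non-copied site
    source = np.maximum.accumulate(np.where(~copied, np.arange(m), -1))
    return fresh[source]


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Phased genotypes for the configured cohort, deterministic under seed."""
    if config.n_snps < 2:
        raise ValueError("need at least 2 SNPs per chromosome")
    rng = _rng(config, 1)
    samples = config.sample_ids()
    n = config.n_samples
    snps: list[SnpRecord] = []
    hap_chunks: list[np.ndarray] = []
    for c in range(config.n_chroms):
        chrom = str(c + 1)
        pos = np.sort(
            rng.choice(config.chrom_length_bp, size=config.n_snps, replace=False)
        ) + 1
        freqs = rng.uniform(config.maf_low, config.maf_high, size=config.n_snps)
        flip = rng.random(config.n_snps) < 0.5
        freqs = np.where(flip, 1.0 - freqs, freqs)  # alt-allele frequency

        def hap() -> np.ndarray:
            return _draw_haplotype(rng, freqs, config.ld_decay)

        haps = np.zeros((n, config.n_snps, 2), dtype=np.int8)
        for j in range(config.n_unrelated):
            haps[j, :, 0] = hap()
            haps[j, :, 1] = hap()
        offset = config.n_unrelated
        for fam_size in (config.n_fam1, config.n_fam2):
            sire = np.stack([hap(), hap()])
            for k in range(fam_size):
                cross = rng.integers(1, config.n_snps)
                which = rng.integers(0, 2)
                paternal = np.concatenate(
                    [sire[which, :cross], sire[1 - which, cross:]]
                )
                haps[offset + k, :, 0] = paternal
                haps[offset + k, :, 1] = hap()  # dam haplotype, unrelated
            offset += fam_size
        dos = haps.sum(axis=2)
        af = dos.mean(axis=0) / 2.0
        for i in range(config.n_snps):
            snps.append(
                SnpRecord(
                    id=f"snp_{chrom}_{pos[i]}",
                    chrom=chrom,
                    pos=int(pos[i]),
                    ref="A",
                    alt="G",
                    maf=float(min(af[i], 1 - af[i])),
                )
            )
        hap_chunks.append(haps)
    haplotypes = np.concatenate(hap_chunks, axis=1)
    return GenotypeMatrix(
        snps=snps,
        samples=samples,
        dosage=haplotypes.sum(axis=2).astype(float),
        phased=True,
        haplotypes=haplotypes,
    )


def simulate_gene_models(
    genotypes: GenotypeMatrix, config: SimConfig
) -> list[GeneModel]:
    """Place gene models on the simulated chromosomes.

    Genes named in ``config.cis_effects`` get a TSS drawn around their
    causal SNP (offset ~ N(0, cis_tss_sd)); all other genes land uniformly.
    Each gene is a simple two-exon model 5 kb long.
    """
    rng = _rng(config, 2)
    snp_by_id = {s.id: s for s in genotypes.snps}
    cis_gene_snp = {}
    for snp_id, gene_id, _ in config.cis_effects:
        if snp_id not in snp_by_id:
            raise ValueError(f"cis effect references unknown SNP {snp_id}")
        cis_gene_snp[gene_id] = snp_by_id[snp_id]
    chroms = [str(c + 1) for c in range(config.n_chroms)]
    genes: list[GeneModel] = []
    for gid in config.gene_ids():
        strand = "+" if rng.random() < 0.5 else "-"
        if gid in cis_gene_snp:
            snp = cis_gene_snp[gid]
            chrom = snp.chrom
            tss = int(snp.pos + round(rng.normal(0.0, config.cis_tss_sd)))
            tss = int(np.clip(tss, 1, config.chrom_length_bp))
        else:
            chrom = chroms[rng.integers(0, len(chroms))]
            tss = int(rng.integers(1, config.chrom_length_bp - 5000))
        start, end = (tss, tss + 4999) if strand == "+" else (max(1, tss - 4999), tss)
        mid = (start + end) // 2
        intervals = [
            (start, mid - 250, "exon"),
            (mid - 249, mid + 249, "intron"),
            (mid + 250, end, "exon"),
        ]
        genes.append(
            GeneModel(gene_id=gid, chrom=chrom, strand=strand, tss=tss,
                      intervals=intervals)
        )
    return genes


def simulate_expression(
    genotypes: GenotypeMatrix, config: SimConfig
) -> tuple[CountMatrix, TruthSet]:
    """Negative-binomial counts with the configured planted structure."""
    rng = _rng(config, 3)
    gene_ids = config.gene_ids()
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    snp_ids = {s.id: i for i, s in enumerate(genotypes.snps)}
    sample_index = {s: i for i, s in enumerate(genotypes.samples)}
    n_genes = len(gene_ids)
    n_samples = genotypes.n_samples

    baseline = np.exp(
        rng.normal(np.log(150.0), 0.7, size=config.n_genes)
    ).clip(min=20.0)
    size_factors = np.exp(rng.normal(0.0, 0.15, size=n_samples))

    log_mean = np.empty((n_genes, n_samples))
    log_mean[: config.n_genes] = np.log(baseline)[:, None]
    # Noise genes come in two parts.  Most are a low-count bulk shared by
    # all samples.  A smaller "shelf" sits just below the configured
    # ceiling and carries a per-sample multiplicative shift, so individual
    # low-expression profiles systematically disagree there; this
    # disagreement is the signal the pairwise KS cutoff search trims, and
    # it dies out once the candidate cutoff passes the shelf, near the
    # ceiling.
    m = config.noise_mean_max
    n_noise = config.n_noise_genes
    n_shelf = int(round(0.4 * n_noise))
    bulk = rng.uniform(0.02 * m, 0.5 * m, size=n_noise - n_shelf)
    shelf = rng.normal(0.8 * m, 0.04 * m, size=n_shelf).clip(0.1 * m, 0.95 * m)
    shift = rng.normal(0.0, config.noise_shift_sd, size=n_samples)
    log_mean[config.n_genes : config.n_genes + len(bulk)] = (
        np.log(bulk)[:, None]
    )
    log_mean[config.n_genes + len(bulk):] = (
        np.log(shelf)[:, None] + shift[None, :]
    )
    log_mean += np.log(size_factors)[None, :]
    dosage = genotypes.dosage_imputed()

    for snp_id, gene_id, fc in config.cis_effects:
        if gene_id not in gene_index:
            raise ValueError(f"cis effect references unknown gene {gene_id}")
        if snp_id not in snp_ids:
            raise ValueError(f"cis effect references unknown SNP {snp_id}")
        log_mean[gene_index[gene_id]] += np.log(fc) * dosage[:, snp_ids[snp_id]]

    hotspot_genes: list[str] = []
    hotspot_snp = None
    if config.hotspot is not None:
        hotspot_snp, n_targets, fc = config.hotspot
        if hotspot_snp not in snp_ids:
            raise ValueError(f"hotspot references unknown SNP {hotspot_snp}")
        cis_genes = {g for _, g, _ in config.cis_effects}
        candidates = [g for g in gene_ids[: config.n_genes] if g not in cis_genes]
        hotspot_genes = list(rng.choice(candidates, size=n_targets, replace=False))
        d = dosage[:, snp_ids[hotspot_snp]]
        for g in hotspot_genes:
            log_mean[gene_index[g]] += np.log(fc) * d

    batch_scores = None
    if config.n_batch_factors > 0:
        k = config.n_batch_factors
        batch_scores = rng.standard_normal((k, n_samples))
        affected = rng.random((n_genes, k)) < config.batch_affected_frac
        loadings = rng.normal(0.0, config.batch_loading_sd, size=(n_genes, k))
        loadings *= affected
        log_mean += loadings @ batch_scores

    for sample_id, gene_id, mult in config.outliers:
        if sample_id not in sample_index or gene_id not in gene_index:
            raise ValueError(f"outlier references unknown ids ({sample_id}, {gene_id})")
        log_mean[gene_index[gene_id], sample_index[sample_id]] += np.log(mult)

    mu = np.exp(log_mean)
    alpha = config.nb_dispersion
    if alpha > 0:
        r = 1.0 / alpha
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)

    truth = TruthSet(
        cis_pairs=list(config.cis_effects),
        hotspot_snp=hotspot_snp,
        hotspot_genes=hotspot_genes,
        outliers=list(config.outliers),
        pheno_snps=list(config.pheno_snps),
        noise_genes=gene_ids[config.n_genes:],
        batch_scores=batch_scores,
    )
    return (
        CountMatrix(gene_ids=gene_ids, sample_ids=list(genotypes.samples),
                    counts=counts),
        truth,
    )


def simulate_phenotype(
    genotypes: GenotypeMatrix, config: SimConfig, max_redraws: int = 10
) -> pd.DataFrame:
    """Covariate table with a Bernoulli disease status driven by a few SNPs.

    status ~ Bernoulli(logistic(intercept + sum beta_k dosage_k + family
    offsets)); sex and age are drawn independently of status.  An all-case
    or all-control draw is retried up to ``max_redraws`` times.
    """
    rng = _rng(config, 4)
    snp_ids = {s.id: i for i, s in enumerate(genotypes.snps)}
    for snp_id, _ in config.pheno_snps:
        if snp_id not in snp_ids:
            raise ValueError(f"phenotype references unknown SNP {snp_id}")
    n = genotypes.n_samples
    dosage = genotypes.dosage_imputed()
    fam1 = np.array([s.startswith("F1_") for s in genotypes.samples], dtype=int)
    fam2 = np.array([s.startswith("F2_") for s in genotypes.samples], dtype=int)
    eta = np.full(n, config.pheno_intercept, dtype=float)
    eta += config.fam1_offset * fam1 + config.fam2_offset * fam2
    for snp_id, beta in config.pheno_snps:
        eta += beta * dosage[:, snp_ids[snp_id]]
    prob = expit(eta)
    status = None
    for _ in range(max_redraws):
        draw = (rng.random(n) < prob).astype(int)
        if 0 < draw.sum() < n:
            status = draw
            break
    if status is None:
        raise RuntimeError(
            f"degenerate phenotype: all-case or all-control after {max_redraws} draws"
        )
    sex = rng.integers(0, 2, size=n)
    age = np.round(rng.uniform(6.0, 32.0, size=n), 1)
    return pd.DataFrame(
        {
            "sample_id": genotypes.samples,
            "sex": sex,
            "age": age,
            "fam1": fam1,
            "fam2": fam2,
            "status": status,
        }
    )
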