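"""Additive linear eQTL scan over all SNP x gene pairs.

For each pair the model is y = mu + m*u + eps, with y the residualized,
variance-stabilized expression of one gene and m the 0/1/2 dosage of one
SNP.  The scan centers both variables, computes the sample correlation r,
and converts it to the OLS slope, t statistic (t = r sqrt(n-2) /
sqrt(1 - r^2)) and two-sided Student-t p-value — algebraically identical
to fitting the regression per pair, but vectorized over the whole grid.

A SNP is cis for a gene when it lies on the same chromosome within
``cis_dist`` of the transcription start site (boundary inclusive); all
other pairs are trans.  Benjamini-Hochberg FDR is computed separately
within the cis and the trans stream, and the best (lowest-FDR) eSNP per
gene can be extracted to represent each gene's eQTL.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exprprep import ResidualMatrix
from .io_formats import GeneModel, GenotypeMatrix, SnpRecord

logger = logging.getLogger(__name__)

_P_FLOOR = float(np.finfo(np.float64).tiny)
_X_CHROMS = {"X", "chrX", "x", "32"}


@dataclass
class ScanConfig:
    cis_dist: int = 1_000_000
    fdr_threshold: float = 0.05
    min_nonmissing: int = 10
    mode: str = "both"  # cis | trans | both
    p_max: float = 1.0  # report only pairs with p <= p_max (FDR uses all)

    def __post_init__(self) -> None:
        if self.cis_dist <= 0:
            raise ValueError("cis_dist must be positive")
        if self.mode not in ("cis", "trans", "both"):
            raise ValueError(f"unknown mode {self.mode!r}")


def classify_pair(snp: SnpRecord, gene: GeneModel, cis_dist: int = 1_000_000) -> str:
    """'cis' iff the SNP is within cis_dist of the gene's TSS on its chromosome."""
    if snp.chrom == gene.chrom and abs(snp.pos - gene.tss) <= cis_dist:
        return "cis"
    return "trans"


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR (q-values), preserving input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def scan(
    residuals: ResidualMatrix,
    genos: GenotypeMatrix,
    genes: list[GeneModel],
    config: ScanConfig | None = None,
) -> pd.DataFrame:
    """All-pairs linear eQTL scan; returns the eQTL table.

    Columns: snp, gene, class, beta, tstat, pvalue, fdr, confidence
    (initialized 'unset') plus the signed SNP-to-TSS distance (NaN for
    different chromosomes).  X-chromosome SNPs and genes are excluded.
    Zero-variance or overly missing SNPs are skipped and counted.
    """
    config = config or ScanConfig()
    gene_by_id = {g.gene_id: g for g in genes}
    keep_genes = [
        i for i, gid in enumerate(residuals.gene_ids)
        if gid in gene_by_id and gene_by_id[gid].chrom not in _X_CHROMS
    ]
    if not keep_genes:
        raise ValueError("no scannable genes (missing models or all on X)")
    sample_pos = {s: i for i, s in enumerate(genos.samples)}
    try:
        order = [sample_pos[s] for s in residuals.sample_ids]
    except KeyError as exc:
        raise ValueError(f"sample {exc} missing from genotypes") from exc

    observed = ~np.isnan(genos.dosage[order])
    dosage = genos.dosage_imputed()[order]
    keep_snps = []
    n_zero_var = n_low_n = 0
    for j, snp in enumerate(genos.snps):
        if snp.chrom in _X_CHROMS:
            continue
        if observed[:, j].sum() < config.min_nonmissing:
            n_low_n += 1
            continue
        if np.ptp(dosage[:, j]) == 0:
            n_zero_var += 1
            continue
        keep_snps.append(j)
    if n_zero_var or n_low_n:
        logger.info(
            "scan skipped %d zero-variance and %d low-call SNPs", n_zero_var, n_low_n
        )
    if not keep_snps:
        raise ValueError("no scannable SNPs")

    Y = residuals.residuals[keep_genes]
    G = dosage[:, keep_snps]
    n = G.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    Yc = Y - Y.mean(axis=1, keepdims=True)
    Gc = G - G.mean(axis=0, keepdims=True)
    sy = np.sqrt((Yc**2).sum(axis=1))
    sg = np.sqrt((Gc**2).sum(axis=0))
    sy_safe = np.where(sy == 0, 1.0, sy)
    R = (Yc @ Gc) / np.outer(sy_safe, sg)
    R[sy == 0, :] = 0.0
    R = np.clip(R, -1.0, 1.0)
    denom = np.maximum(1.0 - R**2, 1e-300)
    tstat = R * np.sqrt((n - 2) / denom)
    pval = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    pval = np.maximum(pval, _P_FLOOR)
    beta = R * (sy[:, None] / sg[None, :])

    snp_chrom = np.array([genos.snps[j].chrom for j in keep_snps])
    snp_pos = np.array([genos.snps[j].pos for j in keep_snps])
    gene_ids = [residuals.gene_ids[i] for i in keep_genes]
    gene_chrom = np.array([gene_by_id[g].chrom for g in gene_ids])
    gene_tss = np.array([gene_by_id[g].tss for g in gene_ids])

    same_chrom = gene_chrom[:, None] == snp_chrom[None, :]
    signed_dist = snp_pos[None, :] - gene_tss[:, None]
    is_cis = same_chrom & (np.abs(signed_dist) <= config.cis_dist)

    gene_grid, snp_grid = np.meshgrid(
        np.arange(len(gene_ids)), np.arange(len(keep_snps)), indexing="ij"
    )
    flat = {
        "gene_i": gene_grid.ravel(),
        "snp_i": snp_grid.ravel(),
        "beta": beta.ravel(),
        "tstat": tstat.ravel(),
        "pvalue": pval.ravel(),
        "is_cis": is_cis.ravel(),
        "distance": np.where(same_chrom, signed_dist, np.nan).ravel(),
    }
    frames = []
    wanted = {"cis": [True], "trans": [False], "both": [True, False]}[config.mode]
    for cis_flag in wanted:
        mask = flat["is_cis"] == cis_flag
        if not mask.any():
            continue
        sub = {k: v[mask] for k, v in flat.items()}
        fdr = bh_fdr(sub["pvalue"])
        report = sub["pvalue"] <= config.p_max
        snp_names = np.array([genos.snps[keep_snps[j]].id for j in sub["snp_i"]])
        frames.append(
            pd.DataFrame(
                {
                    "snp": snp_names[report],
                    "gene": np.array(gene_ids, dtype=object)[sub["gene_i"][report]],
                    "class": "cis" if cis_flag else "trans",
                    "beta": sub["beta"][report],
                    "tstat": sub["tstat"][report],
                    "pvalue": sub["pvalue"][report],
                    "fdr": fdr[report],
                    "confidence": "unset",
                    "distance": sub["distance"][report],
                }
            )
        )
    if not frames:
        raise ValueError(f"no {config.mode} pairs to test")
    return pd.concat(frames, ignore_index=True)


def best_per_gene(table: pd.DataFrame) -> pd.DataFrame:
    """One record per gene: lowest FDR, ties by raw p, |distance|, SNP id."""
    if table.empty:
        return table.copy()
    work = table.copy()
    work["_absdist"] = (
        work["distance"].abs() if "distance" in work else np.inf
    )
    work["_absdist"] = work["_absdist"].fillna(np.inf)
    work = work.sort_values(
        ["gene", "fdr", "pvalue", "_absdist", "snp"], kind="mergesort"
    )
    out = work.groupby("gene", sort=True).head(1).drop(columns="_absdist")
    return out.reset_index(drop=True)


def significant(table: pd.DataFrame, fdr_threshold: float = 0.05) -> pd.DataFrame:
    return table[table["fdr"] < fdr_threshold].reset_index(drop=True)
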