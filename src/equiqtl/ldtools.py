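"""Linkage disequilibrium measures and greedy windowed tag-SNP selection.

LD is quantified on phased haplotypes: D is the haplotype-frequency
covariance p_AB - p_A p_B, D' is D normalized by its frequency-constrained
extreme, and r^2 is the squared haplotype correlation
D^2 / (p_A (1-p_A) p_B (1-p_B)).

Tag SNPs are selected greedily per chromosome: repeatedly pick the
uncovered SNP that covers the most uncovered SNPs at r^2 >= threshold
within +/- window_bp of itself (ties broken by lowest position), until
every SNP above the MAF floor is a tag or covered by one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import GenotypeMatrix


@dataclass
class LdResult:
    D: float
    Dprime: float
    r2: float
    hap_counts: np.ndarray  # 2x2: [[n_AB, n_Ab], [n_aB, n_ab]] (1 = alt)


@dataclass
class TagSet:
    tags: list[str]
    represented: dict[str, list[str]]
    window_bp: int
    r2_threshold: float


def haplotype_ld(hap_a: np.ndarray, hap_b: np.ndarray) -> LdResult:
    """D, D' and r^2 from two binary haplotype vectors of equal length."""
    a = np.asarray(hap_a, dtype=float)
    b = np.asarray(hap_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("haplotype vectors must be equal-length 1-D, length >= 2")
    p_a = a.mean()
    p_b = b.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("monomorphic site: LD undefined")
    p_ab = (a * b).mean()
    D = p_ab - p_a * p_b
    if D >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    dprime = D / d_max if d_max > 0 else 0.0
    r2 = D * D / (p_a * (1 - p_a) * p_b * (1 - p_b))
    counts = np.array(
        [
            [np.sum((a == 1) & (b == 1)), np.sum((a == 1) & (b == 0))],
            [np.sum((a == 0) & (b == 1)), np.sum((a == 0) & (b == 0))],
        ],
        dtype=int,
    )
    return LdResult(D=float(D), Dprime=float(dprime), r2=float(r2),
                    hap_counts=counts)


def _hap_matrix(genos: GenotypeMatrix) -> np.ndarray:
    """Haplotypes as a (2 * samples) x SNPs binary matrix."""
    if not genos.phased or genos.haplotypes is None:
        raise ValueError(
            "tag selection needs phased haplotypes; phase the input or use a "
            "dosage-r2 fallback"
        )
    h = genos.haplotypes
    return h.transpose(0, 2, 1).reshape(-1, h.shape[1]).astype(float)


def select_tag_snps(
    genos: GenotypeMatrix,
    window_bp: int = 100_000,
    r2_threshold: float = 0.99,
    maf_min: float = 0.05,
) -> TagSet:
    """Greedy maximal-coverage tag-SNP selection per chromosome."""
    haps = _hap_matrix(genos)
    maf = np.array([s.maf for s in genos.snps])
    eligible = np.nonzero(maf > maf_min)[0]
    tags: list[str] = []
    represented: dict[str, list[str]] = {}
    chroms = sorted({genos.snps[i].chrom for i in eligible})
    for chrom in chroms:
        idx = np.array(
            [i for i in eligible if genos.snps[i].chrom == chrom], dtype=int
        )
        pos = np.array([genos.snps[i].pos for i in idx])
        order = np.argsort(pos, kind="mergesort")
        idx, pos = idx[order], pos[order]
        m = idx.size
        H = haps[:, idx]
        Hc = H - H.mean(axis=0)
        norms = np.sqrt((Hc**2).sum(axis=0))
        norms[norms == 0] = np.nan
        corr = (Hc.T @ Hc) / np.outer(norms, norms)
        r2 = corr**2
        in_window = np.abs(pos[:, None] - pos[None, :]) <= window_bp
        covers = (r2 >= r2_threshold) & in_window
        np.fill_diagonal(covers, True)
        uncovered = np.ones(m, dtype=bool)
        while uncovered.any():
            gain = (covers & uncovered[None, :]).sum(axis=1)
            gain[~uncovered] = -1  # tags must themselves be uncovered
            best = int(np.flatnonzero(gain == gain.max())[0])  # lowest position
            newly = covers[best] & uncovered
            tag_id = genos.snps[idx[best]].id
            tags.append(tag_id)
            represented[tag_id] = [genos.snps[idx[j]].id for j in np.nonzero(newly)[0]]
            uncovered &= ~newly
    return TagSet(
        tags=tags, represented=represented,
        window_bp=window_bp, r2_threshold=r2_threshold,
    )


def subset_to_tags(genos: GenotypeMatrix, tag_set: TagSet) -> GenotypeMatrix:
    """Restrict a genotype matrix to the selected tag SNPs."""
    keep = set(tag_set.tags)
    mask = np.array([s.id in keep for s in genos.snps])
    return GenotypeMatrix(
        snps=[s for s, k in zip(genos.snps, mask) if k],
        samples=list(genos.samples),
        dosage=genos.dosage[:, mask],
        phased=genos.phased,
        haplotypes=None if genos.haplotypes is None else genos.haplotypes[:, mask],
    )
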