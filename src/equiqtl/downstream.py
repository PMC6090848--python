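"""Downstream analyses of the eQTL tables.

Covers cross-treatment sharing of regulated genes, the -log10 p-value
matrix behind the cross-treatment heatmap, eSNP distance distributions
with a random-window null, TSS-proximity enrichment of cis eSNPs,
trans-regulatory hotspot detection against the local tag-SNP density,
and the two-proportion z-test on genic eSNP fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneModel, SnpRecord

logger = logging.getLogger(__name__)


@dataclass
class HotspotRecord:
    snp_id: str
    trans_gene_count: int
    target_genes: list[str]
    background_density: float  # tag SNPs in this SNP's bin / total tags
    enrichment_p: float


def _snp_map(snps) -> dict[str, SnpRecord]:
    if isinstance(snps, dict):
        return snps
    return {s.id: s for s in snps}


def treatment_overlap(
    sets: dict[str, pd.DataFrame],
) -> tuple[dict[int, int], dict[str, list[str]]]:
    """Partition genes with a significant eQTL by how many treatments share them.

    ``sets`` maps treatment label -> significant best-per-gene table.
    Returns (counts keyed by number of treatments, gene memberships keyed
    by treatment-count label).
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 treatments")
    gene_sets = {t: set(tab["gene"]) for t, tab in sets.items()}
    union = set().union(*gene_sets.values())
    if not union:
        raise ValueError("no significant genes in any treatment")
    membership_count = {
        g: sum(g in s for s in gene_sets.values()) for g in union
    }
    counts = {k: 0 for k in range(1, len(sets) + 1)}
    members: dict[str, list[str]] = {str(k): [] for k in counts}
    for g, k in membership_count.items():
        counts[k] += 1
        members[str(k)].append(g)
    for k in members:
        members[k].sort()
    return counts, members


def pvalue_matrix(
    sets: dict[str, pd.DataFrame],
    raw_p_max: float = 1e-2,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """-log10 raw p per (gene, treatment) for comparably measured eQTLs.

    Rows are genes with a significant eQTL in at least one treatment whose
    raw p-value is strictly below ``raw_p_max`` in every treatment.
    """
    treatments = list(sets)
    pmat = pd.DataFrame(
        {t: tab.set_index("gene")["pvalue"] for t, tab in sets.items()}
    )
    sig_any = pd.DataFrame(
        {t: tab.set_index("gene")["fdr"] < fdr_threshold for t, tab in sets.items()}
    ).fillna(False).any(axis=1)
    keep = sig_any & (pmat < raw_p_max).all(axis=1) & pmat.notna().all(axis=1)
    return -np.log10(pmat.loc[keep, treatments])


def esnp_distance_null(
    snp_positions: np.ndarray,
    n_windows: int = 100,
    window_bp: int = 2_000_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Pairwise SNP distances pooled over random fixed-width windows.

    Draws ``n_windows`` uniform window starts along the span of
    ``snp_positions`` (one chromosome, sorted) and pools |pos_i - pos_j|
    over all SNP pairs inside each window.
    """
    pos = np.sort(np.asarray(snp_positions))
    if pos.size == 0 or pos[-1] <= window_bp:
        raise ValueError("chromosome shorter than one window")
    rng = rng if rng is not None else np.random.default_rng(seed)
    out: list[np.ndarray] = []
    max_start = int(pos[-1]) - window_bp
    for _ in range(n_windows):
        start = int(rng.integers(1, max_start + 1))
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, start + window_bp, side="right")
        w = pos[lo:hi]
        if w.size < 2:
            continue
        d = np.abs(w[:, None] - w[None, :])
        out.append(d[np.triu_indices(w.size, k=1)])
    if not out:
        return np.array([], dtype=float)
    return np.concatenate(out).astype(float)


def shared_gene_esnp_distances(
    sets: dict[str, pd.DataFrame],
    snps,
    null_distances: np.ndarray | None = None,
) -> tuple[np.ndarray, float | None, float | None]:
    """Distances between best eSNPs of genes shared across all treatments.

    For every gene significant in all treatments, and every treatment pair
    whose best eSNPs differ but share a chromosome, record |posA - posB|.
    When a null sample is supplied, a two-sided two-sample KS test compares
    the observed distances with the null; with fewer than 10 observed
    distances the test is skipped.
    """
    snp_by_id = _snp_map(snps)
    treatments = list(sets)
    shared = set.intersection(*(set(tab["gene"]) for tab in sets.values()))
    best = {t: tab.set_index("gene")["snp"] for t, tab in sets.items()}
    dists: list[float] = []
    for gene in shared:
        for i, ta in enumerate(treatments):
            for tb in treatments[i + 1:]:
                sa, sb = best[ta][gene], best[tb][gene]
                if sa == sb:
                    continue
                ra, rb = snp_by_id[sa], snp_by_id[sb]
                if ra.chrom == rb.chrom:
                    dists.append(abs(ra.pos - rb.pos))
    observed = np.array(dists, dtype=float)
    if null_distances is None or observed.size < 10:
        if observed.size < 10:
            logger.warning(
                "only %d eSNP distances; KS test skipped", observed.size
            )
        return observed, None, None
    ks = stats.ks_2samp(observed, null_distances)
    return observed, float(ks.statistic), float(ks.pvalue)


def tss_enrichment(
    cis_table: pd.DataFrame,
    genes: list[GeneModel],
    snps,
    cis_dist: int = 1_000_000,
) -> tuple[np.ndarray, float, float]:
    """Signed eSNP-to-TSS distances vs a uniform cis window (one-sample KS)."""
    if cis_table.empty:
        raise ValueError("empty cis table")
    snp_by_id = _snp_map(snps)
    gene_by_id = {g.gene_id: g for g in genes}
    dists = []
    for rec in cis_table.itertuples(index=False):
        snp = snp_by_id[rec.snp]
        gene = gene_by_id[rec.gene]
        d = snp.pos - gene.tss
        if snp.chrom != gene.chrom or abs(d) > cis_dist:
            raise ValueError(
                f"record ({rec.snp}, {rec.gene}) outside the cis window: "
                "classification bug"
            )
        dists.append(d)
    distances = np.array(dists, dtype=float)
    ks = stats.kstest(distances, "uniform", args=(-cis_dist, 2 * cis_dist))
    return distances, float(ks.statistic), float(ks.pvalue)


def trans_hotspots(
    trans_table: pd.DataFrame,
    tag_positions: dict[str, np.ndarray],
    snps,
    bin_bp: int = 1_000_000,
) -> list[HotspotRecord]:
    """Rank SNPs by trans target count with a binomial enrichment p-value.

    Under proportional allocation, each trans record lands in a genomic bin
    with probability equal to that bin's share of tag SNPs; a SNP's count
    is tested against the binomial expectation for its bin (one-sided).
    """
    if trans_table.empty:
        raise ValueError("empty trans table")
    snp_by_id = _snp_map(snps)
    total_tags = sum(len(v) for v in tag_positions.values())
    if total_tags == 0:
        raise ValueError("no tag positions supplied")
    n_records = len(trans_table)
    grouped = trans_table.groupby("snp")["gene"].apply(list)
    records = []
    for snp_id, targets in grouped.items():
        snp = snp_by_id[snp_id]
        pos_on_chrom = np.asarray(tag_positions.get(snp.chrom, ()))
        bin_lo = (snp.pos // bin_bp) * bin_bp
        in_bin = int(
            ((pos_on_chrom >= bin_lo) & (pos_on_chrom < bin_lo + bin_bp)).sum()
        )
        density = max(in_bin, 1) / total_tags
        test = stats.binomtest(
            len(targets), n=n_records, p=density, alternative="greater"
        )
        records.append(
            HotspotRecord(
                snp_id=snp_id,
                trans_gene_count=len(targets),
                target_genes=sorted(targets),
                background_density=density,
                enrichment_p=float(test.pvalue),
            )
        )
    records.sort(key=lambda r: (-r.trans_gene_count, r.enrichment_p, r.snp_id))
    return records


def _genic_lookup(genes: list[GeneModel]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Merged genic intervals (any feature of any gene) per chromosome."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        for start, end, _ in g.intervals:
            by_chrom.setdefault(g.chrom, []).append((start, end))
    lookup = {}
    for chrom, ivals in by_chrom.items():
        merged: list[list[int]] = []
        for s, e in sorted(ivals):
            if merged and s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        arr = np.array(merged)
        lookup[chrom] = (arr[:, 0], arr[:, 1])
    return lookup


def is_genic(snp: SnpRecord, lookup) -> bool:
    if snp.chrom not in lookup:
        return False
    starts, ends = lookup[snp.chrom]
    i = np.searchsorted(starts, snp.pos, side="right") - 1
    return i >= 0 and snp.pos <= ends[i]


def two_proportion_ztest(x1: int, n1: int, x2: int, n2: int):
    """Pooled two-proportion z test (two-sided)."""
    if n1 == 0 or n2 == 0:
        raise ValueError("zero denominator")
    p1, p2 = x1 / n1, x2 / n2
    pool = (x1 + x2) / (n1 + n2)
    var = pool * (1 - pool) * (1 / n1 + 1 / n2)
    if var == 0:
        return 0.0, 1.0
    z = (p1 - p2) / np.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def genic_proportion_ztest(
    cis_table: pd.DataFrame,
    trans_table: pd.DataFrame,
    genes: list[GeneModel],
    snps,
) -> tuple[float, float, float, float]:
    """Compare the genic fraction of cis vs trans eSNPs.

    An eSNP is genic when its position falls inside any 5UTR/exon/intron/
    3UTR interval of any gene.  Returns (prop_cis, prop_trans, z, p).
    """
    snp_by_id = _snp_map(snps)
    lookup = _genic_lookup(genes)

    def count(table: pd.DataFrame) -> tuple[int, int]:
        esnps = table["snp"].unique()
        genic = sum(is_genic(snp_by_id[s], lookup) for s in esnps)
        return int(genic), len(esnps)

    x1, n1 = count(cis_table)
    x2, n2 = count(trans_table)
    z, p = two_proportion_ztest(x1, n1, x2, n2)
    return x1 / n1, x2 / n2, z, p
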