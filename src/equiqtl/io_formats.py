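"""Readers, writers and container types for the pipeline's standard formats.

Genotypes come in as VCF (biallelic SNPs only) and are held as a samples x
SNPs dosage matrix on the 0/1/2 scale (0 = homozygous reference, 1 =
heterozygous, 2 = homozygous alternative).  Gene models come from GFF3 or
BED12 and carry the strand-aware transcription start site plus labelled
5UTR/exon/intron/3UTR intervals.  All coordinates are 1-based, closed
intervals; signed SNP-to-TSS distances are ``pos - tss``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

EQTL_COLUMNS = ["snp", "gene", "class", "beta", "tstat", "pvalue", "fdr", "confidence"]


class EmptyResultError(ValueError):
    """Raised when a filter leaves nothing to analyse."""


class FormatError(ValueError):
    """Raised on malformed input files."""


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic SNP with its minor allele frequency."""

    id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    maf: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP {self.id}: pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"SNP {self.id}: ref == alt ({self.ref})")
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"SNP {self.id}: maf {self.maf} outside [0, 0.5]")


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix with SNP metadata.

    ``dosage`` is float so missing genotypes can be NaN; observed entries are
    0, 1 or 2.  When ``phased``, ``haplotypes`` is samples x SNPs x 2 binary
    and dosage equals the haplotype sum at every observed site.
    """

    snps: list[SnpRecord]
    samples: list[str]
    dosage: np.ndarray
    phased: bool = False
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.samples)}, {len(self.snps)})"
            )
        if self.phased:
            if self.haplotypes is None:
                raise ValueError("phased=True requires haplotypes")
            if self.haplotypes.shape != self.dosage.shape + (2,):
                raise ValueError("haplotype shape inconsistent with dosage")
            hap_sum = self.haplotypes.sum(axis=2)
            obs = ~np.isnan(self.dosage)
            if not np.array_equal(hap_sum[obs], self.dosage[obs]):
                raise ValueError("dosage != haplotype sum at observed sites")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_index(self, snp_id: str) -> int:
        try:
            return next(i for i, s in enumerate(self.snps) if s.id == snp_id)
        except StopIteration:
            raise KeyError(snp_id) from None

    def dosage_imputed(self) -> np.ndarray:
        """Dosage with missing entries replaced by the per-site mean."""
        d = self.dosage.copy()
        miss = np.isnan(d)
        if miss.any():
            means = np.nanmean(d, axis=0)
            d[miss] = np.take(means, np.nonzero(miss)[1])
            logger.info("mean-imputed %d missing genotype calls", int(miss.sum()))
        return d


@dataclass
class GeneModel:
    """A gene with strand, TSS and labelled feature intervals (1-based closed)."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    intervals: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        for start, end, feat in self.intervals:
            if end < start:
                raise ValueError(
                    f"gene {self.gene_id}: empty interval ({start}, {end}, {feat})"
                )


@dataclass
class CountMatrix:
    """Raw RNA-seq gene counts, genes x samples, non-negative integers."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("counts shape inconsistent with ids")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


COVARIATE_COLUMNS = ["sample_id", "sex", "age", "fam1", "fam2", "status"]


def validate_covariates(covars: pd.DataFrame) -> pd.DataFrame:
    """Check a covariate table (sex/age/Fam1/Fam2/status) for consistency."""
    missing = set(COVARIATE_COLUMNS) - set(covars.columns)
    if missing:
        raise ValueError(f"covariate table missing columns: {sorted(missing)}")
    if ((covars["fam1"] == 1) & (covars["fam2"] == 1)).any():
        raise ValueError("fam1 and fam2 both 1 for some sample")
    for col in ("sex", "fam1", "fam2", "status"):
        if not covars[col].isin((0, 1)).all():
            raise ValueError(f"{col} must be 0/1")
    return covars


# ---------------------------------------------------------------------------
# Hardy-Weinberg tests


def hwe_chisq_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Chi-square (1 df) goodness-of-fit p-value for Hardy-Weinberg equilibrium."""
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    p = (2 * n_hom_ref + n_het) / (2 * n)
    q = 1.0 - p
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    nz = expected > 0
    chi2 = float(((observed[nz] - expected[nz]) ** 2 / expected[nz]).sum())
    return float(stats.chi2.sf(chi2, df=1))


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg p-value (sum of heterozygote-count probabilities
    no larger than the observed one, conditional on allele counts)."""
    n = n_hom_ref + n_het + n_hom_alt
    n_rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n == 0:
        return 1.0
    # log-probability of each compatible heterozygote count
    het_values = range(n_rare % 2, n_rare + 1, 2)
    logps = []
    for h in het_values:
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        lp = (
            h * math.log(2)
            + math.lgamma(n + 1)
            - math.lgamma(rare_hom + 1)
            - math.lgamma(h + 1)
            - math.lgamma(common_hom + 1)
            + math.lgamma(n_rare + 1)
            + math.lgamma(2 * n - n_rare + 1)
            - math.lgamma(2 * n + 1)
        )
        logps.append(lp)
    probs = np.exp(np.array(logps) - max(logps))
    probs /= probs.sum()
    obs_het = min(n_het, n_rare)
    p_obs = probs[list(het_values).index(obs_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# VCF genotypes


def read_genotypes(
    path: str,
    maf_min: float = 0.05,
    hwe_alpha: float = 1e-6,
    status: dict[str, int] | None = None,
    max_missing: float = 0.10,
    hwe_exact: bool = False,
) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a dosage matrix with QC filters.

    Sites are dropped when multiallelic or non-SNP, when more than
    ``max_missing`` of genotypes are missing, when MAF < ``maf_min`` or when
    the Hardy-Weinberg p-value is <= ``hwe_alpha``.  When a ``status`` map
    (sample id -> 0/1) is given, HWE is evaluated in controls (status 0)
    only.  Filter counts are logged.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    control_mask = None
    if status is not None:
        control_mask = np.array([status.get(s, 1) == 0 for s in samples])
        if not control_mask.any():
            control_mask = None
            logger.warning("no control samples found; HWE uses all samples")

    hwe_p = hwe_exact_p if hwe_exact else hwe_chisq_p
    snps: list[SnpRecord] = []
    dosage_cols: list[np.ndarray] = []
    hap_cols: list[np.ndarray] = []
    all_phased = True
    n_multi = n_miss = n_maf = n_hwe = 0
    for variant in vcf:
        if len(variant.ALT) != 1 or len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
            n_multi += 1
            continue
        gts = np.asarray(variant.gt_types, dtype=float)  # 0/1/2, 3 = missing
        gts[gts == 3] = np.nan
        miss_frac = np.isnan(gts).mean()
        if miss_frac > max_missing:
            n_miss += 1
            continue
        obs = gts[~np.isnan(gts)]
        if obs.size == 0:
            n_miss += 1
            continue
        af = obs.sum() / (2 * obs.size)
        maf = min(af, 1 - af)
        if maf < maf_min:
            n_maf += 1
            continue
        if control_mask is not None:
            g_hwe = gts[control_mask]
            g_hwe = g_hwe[~np.isnan(g_hwe)]
        else:
            g_hwe = obs
        counts = [int((g_hwe == k).sum()) for k in (0, 1, 2)]
        if hwe_p(*counts) <= hwe_alpha:
            n_hwe += 1
            continue
        vid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        snps.append(
            SnpRecord(
                id=vid,
                chrom=variant.CHROM,
                pos=variant.POS,
                ref=variant.REF,
                alt=variant.ALT[0],
                maf=float(maf),
            )
        )
        dosage_cols.append(gts)
        geno = np.array(variant.genotypes, dtype=object)
        phased_here = all(g[2] for g in variant.genotypes) and not np.isnan(gts).any()
        all_phased = all_phased and phased_here
        if phased_here:
            hap_cols.append(np.array([[g[0], g[1]] for g in geno], dtype=np.int8))

    logger.info(
        "VCF %s: kept %d SNPs (dropped %d multiallelic/non-SNP, %d missingness, "
        "%d MAF, %d HWE)",
        path, len(snps), n_multi, n_miss, n_maf, n_hwe,
    )
    if not snps:
        raise EmptyResultError(f"no SNPs in {path} survive the filters")
    dosage = np.column_stack(dosage_cols)
    haplotypes = None
    phased = all_phased and len(hap_cols) == len(snps)
    if phased:
        haplotypes = np.stack(hap_cols, axis=1)
    return GenotypeMatrix(
        snps=snps, samples=samples, dosage=dosage, phased=phased,
        haplotypes=haplotypes,
    )


# ---------------------------------------------------------------------------
# Gene models


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for start, end in sorted(ivals):
        if merged and start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def _introns_from_exons(exons: list[tuple[int, int]]) -> list[tuple[int, int]]:
    introns = []
    for (_, e1), (s2, _) in zip(exons, exons[1:]):
        if s2 > e1 + 1:
            introns.append((e1 + 1, s2 - 1))
    return introns


_GFF_UTR_NAMES = {
    "five_prime_UTR": "5UTR",
    "three_prime_UTR": "3UTR",
    "5UTR": "5UTR",
    "3UTR": "3UTR",
}


def _gff3_attr(field_text: str, *keys: str) -> str | None:
    for part in field_text.strip().split(";"):
        if "=" not in part:
            continue
        k, v = part.split("=", 1)
        if k.strip() in keys:
            return v.strip()
    return None


def read_gene_models(path: str) -> list[GeneModel]:
    """Read gene models from GFF3 (.gff/.gff3) or BED12 (.bed).

    TSS is the gene start on + strand and the gene end on - strand.  Introns
    are the gaps between merged exons inside the gene span.
    """
    lower = str(path).lower()
    if lower.endswith((".bed", ".bed12")):
        return _read_bed12(path)
    return _read_gff3(path)


def _read_gff3(path: str) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    feature_parent: dict[str, str] = {}
    pending: list[tuple[str, int, int, str]] = []  # (parent, start, end, label)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _, ftype, start_s, end_s, _, strand, _, attrs = fields
            start, end = int(start_s), int(end_s)
            if end < start:
                raise FormatError(f"{path}:{lineno}: end < start")
            if ftype == "gene":
                if strand not in ("+", "-"):
                    raise FormatError(f"{path}:{lineno}: gene without strand")
                gid = _gff3_attr(attrs, "ID", "gene_id", "Name")
                if gid is None:
                    raise FormatError(f"{path}:{lineno}: gene without ID")
                genes[gid] = {
                    "chrom": chrom, "strand": strand, "start": start, "end": end,
                    "exons": [], "5UTR": [], "3UTR": [],
                }
            elif ftype in ("mRNA", "transcript"):
                fid = _gff3_attr(attrs, "ID")
                parent = _gff3_attr(attrs, "Parent")
                if fid and parent:
                    feature_parent[fid] = parent
            elif ftype == "exon" or ftype in _GFF_UTR_NAMES:
                parent = _gff3_attr(attrs, "Parent")
                label = "exons" if ftype == "exon" else _GFF_UTR_NAMES[ftype]
                pending.append((parent or "", start, end, label))
    for parent, start, end, label in pending:
        gid = feature_parent.get(parent, parent)
        if gid in genes:
            genes[gid][label if label in ("5UTR", "3UTR") else "exons"].append(
                (start, end)
            )
    return [_assemble_gene(gid, info) for gid, info in genes.items()]


def _assemble_gene(gid: str, info: dict) -> GeneModel:
    strand = info["strand"]
    tss = info["start"] if strand == "+" else info["end"]
    exons = _merge_intervals(info["exons"]) or [(info["start"], info["end"])]
    intervals = [(s, e, "exon") for s, e in exons]
    intervals += [(s, e, "intron") for s, e in _introns_from_exons(exons)]
    intervals += [(s, e, "5UTR") for s, e in _merge_intervals(info["5UTR"])]
    intervals += [(s, e, "3UTR") for s, e in _merge_intervals(info["3UTR"])]
    return GeneModel(
        gene_id=gid, chrom=info["chrom"], strand=strand, tss=tss,
        intervals=sorted(intervals),
    )


def _read_bed12(path: str) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 BED columns")
            chrom, chrom_start, chrom_end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5]
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: missing strand")
            thick_start, thick_end = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            # BED is 0-based half-open; convert to 1-based closed
            exons = []
            for size, off in zip(sizes, starts):
                if size <= 0:
                    raise FormatError(f"{path}:{lineno}: zero-length block")
                s0 = chrom_start + off
                exons.append((s0 + 1, s0 + size))
            exons = _merge_intervals(exons)
            intervals = [(s, e, "exon") for s, e in exons]
            intervals += [(s, e, "intron") for s, e in _introns_from_exons(exons)]
            if thick_end > thick_start:  # annotated CDS: flanks are UTR
                left = [(s, min(e, thick_start)) for s, e in exons if s <= thick_start]
                right = [(max(s, thick_end + 1), e) for s, e in exons if e > thick_end]
                left = [(s, e) for s, e in left if e >= s]
                right = [(s, e) for s, e in right if e >= s]
                five, three = (left, right) if strand == "+" else (right, left)
                intervals += [(s, e, "5UTR") for s, e in five]
                intervals += [(s, e, "3UTR") for s, e in three]
            tss = chrom_start + 1 if strand == "+" else chrom_end
            genes.append(
                GeneModel(
                    gene_id=name, chrom=chrom, strand=strand, tss=tss,
                    intervals=sorted(intervals),
                )
            )
    return genes


# ---------------------------------------------------------------------------
# eQTL tables


def write_eqtl_table(table: pd.DataFrame, path: str) -> None:
    """Write an eQTL table as TSV under a canonical (gene, fdr, snp) sort.

    Refuses to write non-finite statistics; the output is byte-stable for a
    given table.
    """
    missing = set(EQTL_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"eQTL table missing columns: {sorted(missing)}")
    num = table[["beta", "tstat", "pvalue", "fdr"]].to_numpy(dtype=float)
    if len(table) and not np.isfinite(num).all():
        bad = table.index[~np.isfinite(num).any(axis=1) | ~np.isfinite(num).all(axis=1)]
        row = table.loc[bad[0]]
        raise ValueError(
            f"non-finite statistic in row snp={row['snp']} gene={row['gene']}"
        )
    out = table[EQTL_COLUMNS].sort_values(
        ["gene", "fdr", "snp"], kind="mergesort"
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_eqtl_table(path: str) -> pd.DataFrame:
    table = pd.read_csv(
        path, sep="\t",
        dtype={"snp": str, "gene": str, "class": str, "confidence": str},
    )
    missing = set(EQTL_COLUMNS) - set(table.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return table.reset_index(drop=True)
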