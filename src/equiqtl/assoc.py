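"""Case-control logistic GWAS and expression-disease association.

Each SNP is tested with a logistic regression of binary disease status on
intercept + age + sex + Fam1 + Fam2 + dosage, fit by iteratively
reweighted least squares; SNPs are ranked by the Wald p-value of the
dosage term.  Family membership enters as fixed covariates to absorb the
shared-sire structure of the cohort.

For expression-disease models, surrogate variables are derived as the top
principal components of the expression matrix after removing the known
covariates *including* disease status, so latent batch variation is
captured while the status signal itself is protected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exprprep import ExpressionMatrix, _residualize_on
from .io_formats import GenotypeMatrix, validate_covariates

logger = logging.getLogger(__name__)

_BASE_COVARIATES = ["age", "sex", "fam1", "fam2"]


@dataclass
class SurrogateVariables:
    values: np.ndarray  # samples x k
    protected: list[str]
    sample_ids: list[str]


def _design(covars: pd.DataFrame, cols: list[str]) -> np.ndarray:
    # constant columns (e.g. fam1/fam2 in an unrelated-only cohort) carry no
    # information beyond the intercept and are dropped with a note
    varying = [c for c in cols if covars[c].nunique() > 1]
    dropped = sorted(set(cols) - set(varying))
    if dropped:
        logger.info("dropping constant covariate columns: %s", dropped)
    cols = varying
    X = np.column_stack(
        [np.ones(len(covars))] + [covars[c].to_numpy(dtype=float) for c in cols]
    )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = []
        kept = [X[:, :1]]
        names = ["intercept"] + cols
        for j in range(1, X.shape[1]):
            cand = np.column_stack(kept + [X[:, j : j + 1]])
            if np.linalg.matrix_rank(cand) == cand.shape[1]:
                kept.append(X[:, j : j + 1])
            else:
                bad.append(names[j])
        raise ValueError(f"singular design; collinear columns: {bad}")
    return X


def _fit_logistic(y: np.ndarray, X: np.ndarray, term: int = -1):
    """IRLS logistic fit; returns (params, bse, pvalues, converged).

    ``term`` is the coefficient the caller cares about; the fit is flagged
    unconverged when IRLS fails or that term shows signs of
    (quasi-)complete separation (non-finite or absurd standard error).
    A separated *covariate* does not invalidate the term of interest.
    """
    import warnings

    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings(record=True) as wlog:
            warnings.simplefilter("always")
            res = model.fit(maxiter=200, tol=1e-10)
        separated = any("separation" in str(w.message).lower() for w in wlog)
        converged = (
            bool(res.converged)
            and not separated
            and np.isfinite(res.bse[term])
            and res.bse[term] < 50
        )
        return res.params, res.bse, res.pvalues, converged
    except Exception:
        k = X.shape[1]
        return np.full(k, np.nan), np.full(k, np.nan), np.full(k, np.nan), False


def logistic_scan(
    genos: GenotypeMatrix, covars: pd.DataFrame
) -> pd.DataFrame:
    """Per-SNP logistic GWAS; returns records ranked by dosage p-value.

    Samples with missing covariates are removed.  SNPs with constant
    dosage, or fits showing (quasi-)complete separation, are flagged
    unconverged with NaN statistics.
    """
    validate_covariates(covars)
    cov = covars.dropna(subset=_BASE_COVARIATES + ["status"]).copy()
    dropped = len(covars) - len(cov)
    if dropped:
        logger.info("removed %d samples with missing covariates", dropped)
    sample_pos = {s: i for i, s in enumerate(genos.samples)}
    cov = cov[cov["sample_id"].isin(sample_pos)]
    rows = [sample_pos[s] for s in cov["sample_id"]]
    y = cov["status"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("status must include both cases and controls")
    X_base = _design(cov, _BASE_COVARIATES)
    dosage = genos.dosage_imputed()[rows]
    records = []
    for j, snp in enumerate(genos.snps):
        g = dosage[:, j]
        if np.ptp(g) == 0:
            records.append((snp.id, np.nan, np.nan, np.nan, False))
            continue
        X = np.column_stack([X_base, g])
        params, bse, pvals, converged = _fit_logistic(y, X)
        if converged:
            records.append((snp.id, params[-1], bse[-1], pvals[-1], True))
        else:
            records.append((snp.id, np.nan, np.nan, np.nan, False))
    out = pd.DataFrame(
        records, columns=["snp", "beta_g", "se", "pvalue", "converged"]
    )
    return out.sort_values(
        "pvalue", kind="mergesort", na_position="last"
    ).reset_index(drop=True)


def gwas_eqtl_overlap(
    gwas: pd.DataFrame,
    cis_tables: dict[str, pd.DataFrame],
    top_n: int = 15,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Which of the top GWAS SNPs are also significant cis eSNPs, and where."""
    ranked = gwas.dropna(subset=["pvalue"]).sort_values("pvalue", kind="mergesort")
    if top_n > len(ranked):
        logger.warning(
            "top_n=%d exceeds %d ranked GWAS SNPs; using all", top_n, len(ranked)
        )
        top_n = len(ranked)
    top = list(ranked["snp"].head(top_n))
    hits = []
    for treatment, table in cis_tables.items():
        sig = table[table["fdr"] < fdr_threshold]
        for rec in sig.itertuples(index=False):
            if rec.snp in top:
                hits.append((rec.snp, treatment, rec.gene))
    return pd.DataFrame(hits, columns=["snp", "treatment", "gene"])


def surrogate_variables(
    expr: ExpressionMatrix, covars: pd.DataFrame, k: int
) -> SurrogateVariables:
    """Top-k PCs of expression residualized on covariates including status."""
    validate_covariates(covars)
    cov = covars.set_index("sample_id").loc[expr.sample_ids].reset_index()
    cols = _BASE_COVARIATES + ["status"]
    X = _design(cov, cols)
    n = len(expr.sample_ids)
    if k >= n - X.shape[1]:
        raise ValueError(f"k={k} too large for n={n} with {X.shape[1]} covariates")
    if k == 0:
        values = np.empty((n, 0))
    else:
        resid = _residualize_on(expr.values, X)
        _, _, vt = np.linalg.svd(resid, full_matrices=False)
        values = vt[:k].T
    return SurrogateVariables(
        values=values, protected=["intercept"] + cols,
        sample_ids=list(expr.sample_ids),
    )


def expression_disease_assoc(
    gene_values: np.ndarray,
    covars: pd.DataFrame,
    svs: SurrogateVariables | None = None,
) -> tuple[float, float, bool]:
    """Logistic model of status on covariates (+ surrogates) + expression.

    Returns (beta for the expression term, Wald p, converged).
    """
    validate_covariates(covars)
    y = covars["status"].to_numpy(dtype=float)
    X = _design(covars, _BASE_COVARIATES)
    if svs is not None and svs.values.shape[1] > 0:
        X = np.column_stack([X, svs.values])
    X = np.column_stack([X, np.asarray(gene_values, dtype=float)])
    params, _, pvals, converged = _fit_logistic(y, X)
    return float(params[-1]), float(pvals[-1]), converged
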