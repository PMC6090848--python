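"""Confidence classification of eQTLs via influence and assumption checks.

Every significant eQTL is re-fit as the simple regression of residual
expression on dosage.  Two screens decide its label:

* outlier individuals — a sample is an outlier when its Cook's distance
  exceeds 0.5 AND its leverage exceeds 2 p / n (p = number of model
  coefficients, here 2; the conjunction is deliberate);
* a four-component global assumption omnibus — moment-based skewness and
  kurtosis statistics plus score tests for a misspecified link (an added
  squared-fitted-value term) and for heteroscedasticity (squared residuals
  on fitted values), each referred to chi-square(1), summed to a global
  chi-square(4) statistic.

An eQTL with any outlier individual, or whose global omnibus is rejected
at alpha, is labelled low confidence; otherwise high confidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exprprep import ResidualMatrix
from .io_formats import GenotypeMatrix


@dataclass
class DiagnosticsRecord:
    leverage: np.ndarray  # per-sample h_i
    cooks: np.ndarray  # per-sample D_i
    n: int
    p_coef: int
    sample_ids: list[str] | None = None


@dataclass
class AssumptionResult:
    components: dict[str, tuple[float, float]]  # name -> (statistic, p)
    global_stat: float
    global_p: float
    accepted: bool
    alpha: float


def _simple_fit(y: np.ndarray, g: np.ndarray):
    n = y.size
    g_bar = g.mean()
    gc = g - g_bar
    sxx = float(gc @ gc)
    if sxx == 0:
        raise ValueError("constant genotype: no fit")
    slope = float(gc @ y) / sxx
    intercept = y.mean() - slope * g_bar
    fitted = intercept + slope * g
    resid = y - fitted
    return slope, intercept, fitted, resid, gc, sxx


def refit_diagnostics(
    y: np.ndarray, g: np.ndarray, sample_ids: list[str] | None = None
) -> DiagnosticsRecord:
    """Leverage and Cook's distance for the per-pair regression y ~ 1 + g."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    if y.shape != g.shape or y.ndim != 1:
        raise ValueError("y and g must be equal-length vectors")
    n = y.size
    if n < 4:
        raise ValueError("need n >= 4 for diagnostics")
    _, _, _, resid, gc, sxx = _simple_fit(y, g)
    h = 1.0 / n + gc**2 / sxx
    p = 2
    sse = float(resid @ resid)
    s2 = sse / (n - p)
    if s2 == 0:
        cooks = np.zeros(n)
    else:
        cooks = resid**2 * h / (p * s2 * (1.0 - h) ** 2)
    return DiagnosticsRecord(
        leverage=h, cooks=cooks, n=n, p_coef=p, sample_ids=sample_ids
    )


def flag_outliers(
    diag: DiagnosticsRecord,
    cooks_threshold: float = 0.5,
    conjunction: bool = True,
) -> list:
    """Samples with Cook's D > 0.5 and leverage > 2 p / n.

    ``conjunction=False`` switches to the more aggressive either/or rule
    for sensitivity analyses.
    """
    lev_threshold = 2.0 * diag.p_coef / diag.n
    high_d = diag.cooks > cooks_threshold
    high_h = diag.leverage > lev_threshold
    mask = (high_d & high_h) if conjunction else (high_d | high_h)
    idx = np.nonzero(mask)[0]
    if diag.sample_ids is not None:
        return [diag.sample_ids[i] for i in idx]
    return list(idx)


def assumption_omnibus(
    y: np.ndarray, g: np.ndarray, alpha: float = 0.05
) -> AssumptionResult:
    """Four-part global validation of the linear-model assumptions."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    if y.size < 10:
        raise ValueError("need n >= 10 for the omnibus")
    n = y.size
    _, _, fitted, resid, _, _ = _simple_fit(y, g)
    sd = resid.std()
    if sd == 0:
        raise ValueError("degenerate residuals (zero variance)")
    z = resid / sd
    skew = float((z**3).mean())
    kurt = float((z**4).mean())
    stat_skew = n * skew**2 / 6.0
    stat_kurt = n * (kurt - 3.0) ** 2 / 24.0

    def _score_stat(response: np.ndarray, regressors: np.ndarray) -> float:
        # n * R^2 of the auxiliary regression (score / LM form)
        X = np.column_stack([np.ones(n)] + [r for r in regressors.T])
        coef, *_ = np.linalg.lstsq(X, response, rcond=None)
        pred = X @ coef
        tss = float(((response - response.mean()) ** 2).sum())
        if tss == 0:
            return 0.0
        rss = float(((response - pred) ** 2).sum())
        return n * (1.0 - rss / tss)

    # link misspecification: do squared fitted values explain the residuals?
    stat_link = _score_stat(resid, np.column_stack([g, fitted**2]))
    # heteroscedasticity: do fitted values explain the squared residuals?
    stat_het = _score_stat(resid**2, fitted[:, None])

    comps = {
        "skewness": stat_skew,
        "kurtosis": stat_kurt,
        "link_function": stat_link,
        "heteroscedasticity": stat_het,
    }
    components = {
        name: (s, float(stats.chi2.sf(s, df=1))) for name, s in comps.items()
    }
    global_stat = float(sum(comps.values()))
    global_p = float(stats.chi2.sf(global_stat, df=4))
    return AssumptionResult(
        components=components,
        global_stat=global_stat,
        global_p=global_p,
        accepted=global_p > alpha,
        alpha=alpha,
    )


def classify_confidence(
    diag: DiagnosticsRecord, omnibus: AssumptionResult
) -> str:
    """'low' iff any outlier individual or the omnibus is rejected."""
    if flag_outliers(diag) or not omnibus.accepted:
        return "low"
    return "high"


def annotate_confidence(
    table: pd.DataFrame,
    residuals: ResidualMatrix,
    genos: GenotypeMatrix,
    fdr_threshold: float = 0.05,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Populate the confidence column for all significant records.

    Records at or above the FDR threshold keep confidence 'unset'
    (diagnostics are only run where the scan called an eQTL).
    """
    out = table.copy()
    gene_row = {g: i for i, g in enumerate(residuals.gene_ids)}
    sample_pos = {s: i for i, s in enumerate(genos.samples)}
    order = [sample_pos[s] for s in residuals.sample_ids]
    dosage = genos.dosage_imputed()[order]
    snp_col = {s.id: j for j, s in enumerate(genos.snps)}
    labels = []
    for rec in out.itertuples(index=False):
        if rec.fdr >= fdr_threshold:
            labels.append("unset")
            continue
        y = residuals.residuals[gene_row[rec.gene]]
        g = dosage[:, snp_col[rec.snp]]
        diag = refit_diagnostics(y, g, sample_ids=list(residuals.sample_ids))
        omni = assumption_omnibus(y, g, alpha=alpha)
        labels.append(classify_confidence(diag, omni))
    out["confidence"] = labels
    return out
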