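"""In-cis correlation, the log-linear cis model, and in-trans rankings.

The cis model for gene g over samples i is

    e_gi = a_g + b_g * c_gi + eps_gi                                  (log2)

with e the log expression, c the (PCF-derived) log copy number and eps iid
noise.  Ordinary least squares gives per-gene coefficients and residual
expression r_gi = e_gi - a_g - b_g * c_gi; the residuals carry the part of
expression not explained by the gene's own copy number, which removes the
confounding effect of co-occurring aberrations from in-trans correlations.

In-cis correlation is the per-gene Pearson correlation between c and e.  The
empirical FDR for a cis cutoff is estimated by shuffling the gene order of
the copy-number matrix (expression untouched) and recomputing correlations.
The in-trans effect of a pivot gene G on gene g is the Pearson correlation
between G's observed log expression and g's residual expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import DEFAULT_MIN_PAIRS, GeneTable

logger = logging.getLogger("ipac.cistrans")


# ---------------------------------------------------------------------------
# Row-wise Pearson with pairwise-complete observations
# ---------------------------------------------------------------------------

def _rowwise_pearson(A: np.ndarray, B: np.ndarray,
                     min_pairs: int = DEFAULT_MIN_PAIRS) -> np.ndarray:
    """Pearson correlation of A[k, :] with B[k, :] for every row k.

    Pairs with a missing value in either matrix are dropped per row; rows
    with fewer than ``min_pairs`` complete pairs or zero variance give NaN.
    """
    mask = np.isfinite(A) & np.isfinite(B)
    A0 = np.where(mask, A, 0.0)
    B0 = np.where(mask, B, 0.0)
    n = mask.sum(axis=1)
    sa, sb = A0.sum(1), B0.sum(1)
    saa, sbb, sab = (A0 * A0).sum(1), (B0 * B0).sum(1), (A0 * B0).sum(1)
    with np.errstate(invalid="ignore", divide="ignore"):
        nn = np.maximum(n, 1)
        cov = sab - sa * sb / nn
        va = saa - sa * sa / nn
        vb = sbb - sb * sb / nn
        r = cov / np.sqrt(va * vb)
    r = np.where((n >= min_pairs) & (va > 1e-300) & (vb > 1e-300), r, np.nan)
    return np.clip(r, -1.0, 1.0)


def variance_explained_percent(r: float) -> float:
    """Coefficient of determination implied by a Pearson cutoff, in percent.

    The default in-cis selection cutoff r = 0.6 corresponds to 36%: at least
    that share of log-expression variance is accounted for by the in-cis
    variation of log copy number for every selected gene.
    """
    if not -1 <= r <= 1:
        raise ValueError("r must be in [-1, 1]")
    return 100.0 * r * r


def cis_correlation(genes: GeneTable,
                    min_pairs: int = DEFAULT_MIN_PAIRS) -> pd.Series:
    """Per-gene Pearson correlation between log copy number and log expression.

    Genes with too few complete pairs or a zero-variance vector are marked
    missing (NaN) with a warning.
    """
    r = _rowwise_pearson(genes.cn.to_numpy(), genes.expr.to_numpy(), min_pairs)
    n_missing = int(np.isnan(r).sum())
    if n_missing:
        logger.warning("in-cis correlation undefined for %d genes "
                       "(zero variance or < %d complete pairs)",
                       n_missing, min_pairs)
    return pd.Series(r, index=genes.cn.index, name="cis_r")


# ---------------------------------------------------------------------------
# Shuffle-based empirical FDR for a cis cutoff
# ---------------------------------------------------------------------------

@dataclass
class CisFdrResult:
    """Empirical FDR of a cis-correlation cutoff from gene-order shuffles."""

    cutoff: float
    n_observed: int
    mean_null: float
    fdr_estimate: float
    n_shuffles: int


def shuffle_fdr(genes: GeneTable, cutoff: float, n_shuffles: int = 2000,
                seed: int | np.random.Generator = 0,
                min_pairs: int = DEFAULT_MIN_PAIRS,
                restrict: np.ndarray | None = None) -> CisFdrResult:
    """Estimate the FDR of selecting genes with cis_r > cutoff.

    For each shuffle the gene order of the copy-number matrix is permuted
    genome-wide (expression untouched), correlations are recomputed against
    the mismatched rows, and exceedances of the cutoff counted.  The estimate
    is mean null exceedances / max(observed exceedances, 1).

    ``restrict`` optionally limits the *counting* to a boolean gene mask
    (e.g. commonly aberrant genes) while still shuffling the full matrix.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cn = genes.cn.to_numpy()
    expr = genes.expr.to_numpy()
    if restrict is None:
        restrict = np.ones(cn.shape[0], dtype=bool)
    obs = _rowwise_pearson(cn, expr, min_pairs)
    n_observed = int(np.nansum((obs > cutoff) & restrict))
    null_counts = np.empty(n_shuffles)
    for k in range(n_shuffles):
        perm = rng.permutation(cn.shape[0])
        r = _rowwise_pearson(cn[perm], expr, min_pairs)
        null_counts[k] = np.nansum((r > cutoff) & restrict)
    mean_null = float(null_counts.mean())
    return CisFdrResult(cutoff=cutoff, n_observed=n_observed,
                        mean_null=mean_null,
                        fdr_estimate=mean_null / max(n_observed, 1),
                        n_shuffles=n_shuffles)


def select_cis_genes(cis_r: pd.Series, common_table: pd.DataFrame,
                     cutoff: float = 0.6) -> list[str]:
    """Genes that are commonly aberrant AND have cis_r strictly above cutoff.

    One-sided positive: both amplification-driven overexpression and
    deletion-driven underexpression produce positive cis correlation, so
    negative correlations are never selected.
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be in (0, 1)")
    aligned = common_table["commonly_aberrant"].reindex(cis_r.index, fill_value=False)
    keep = aligned.to_numpy(dtype=bool) & (cis_r.to_numpy() > cutoff)
    out = [g for g, k in zip(cis_r.index, keep) if k]
    logger.info("in-cis genes: %d of %d commonly aberrant (r > %g)",
                len(out), int(aligned.sum()), cutoff)
    return out


# ---------------------------------------------------------------------------
# Cis model fit and residual expression
# ---------------------------------------------------------------------------

def fit_cis_model(e: np.ndarray, c: np.ndarray) -> tuple[float, float, np.ndarray]:
    """OLS fit of one gene's cis model; returns (a, b, residuals).

    Residuals are NaN where either input is missing.  With fewer than 3
    complete pairs or zero copy-number variance the slope is 0, the intercept
    the mean expression, and residuals are centered expression (warning).
    """
    e = np.asarray(e, dtype=float)
    c = np.asarray(c, dtype=float)
    mask = np.isfinite(e) & np.isfinite(c)
    n = int(mask.sum())
    degenerate = n < 3 or (n > 0 and np.var(c[mask]) <= 1e-300)
    if n == 0:
        return np.nan, np.nan, np.full_like(e, np.nan)
    if degenerate:
        logger.warning("degenerate cis fit (n=%d complete pairs): slope set to 0", n)
        a = float(e[mask].mean())
        b = 0.0
    else:
        cm = c[mask].mean()
        em = e[mask].mean()
        b = float(((c[mask] - cm) * (e[mask] - em)).sum()
                  / ((c[mask] - cm) ** 2).sum())
        a = float(em - b * cm)
    resid = np.where(mask, e - a - b * c, np.nan)
    return a, b, resid


@dataclass
class CisModelFit:
    """Per-gene cis-model coefficients, residual matrix and cis correlation."""

    coef: pd.DataFrame        # index gene; columns a, b
    residuals: pd.DataFrame   # genes x samples, aligned to expression
    cis_r: pd.Series

    @property
    def genes(self) -> list[str]:
        return list(self.residuals.index)


def residual_matrix(genes: GeneTable,
                    min_pairs: int = DEFAULT_MIN_PAIRS) -> CisModelFit:
    """Fit the cis model for every gene in the universe (not only cis genes).

    Vectorised OLS over rows with pairwise-complete samples.  Genes with
    fewer than max(3, min_pairs) complete pairs or zero copy-number variance
    get slope 0 and centered-expression residuals.
    """
    C = genes.cn.to_numpy(dtype=float)
    E = genes.expr.to_numpy(dtype=float)
    mask = np.isfinite(C) & np.isfinite(E)
    C0 = np.where(mask, C, 0.0)
    E0 = np.where(mask, E, 0.0)
    n = mask.sum(axis=1)
    nn = np.maximum(n, 1)
    cm = C0.sum(1) / nn
    em = E0.sum(1) / nn
    cov = (C0 * E0).sum(1) - nn * cm * em
    var_c = (C0 * C0).sum(1) - nn * cm * cm
    min_n = max(3, min_pairs)
    ok = (n >= min_n) & (var_c > 1e-300)
    with np.errstate(invalid="ignore", divide="ignore"):
        b = np.where(ok, cov / var_c, 0.0)
    a = em - b * cm
    n_deg = int((~ok).sum())
    if n_deg:
        logger.warning("%d genes have degenerate cis fits (slope set to 0)", n_deg)
    resid = np.where(mask, E - a[:, None] - b[:, None] * C, np.nan)
    # degenerate genes: residuals defined wherever expression is present
    if n_deg:
        deg = ~ok
        e_mask = np.isfinite(E[deg])
        e_mean = np.where(e_mask, E[deg], 0.0).sum(1) / np.maximum(e_mask.sum(1), 1)
        resid[deg] = np.where(e_mask, E[deg] - e_mean[:, None], np.nan)
    coef = pd.DataFrame({"a": a, "b": b}, index=genes.cn.index)
    residuals = pd.DataFrame(resid, index=genes.cn.index, columns=genes.samples)
    return CisModelFit(coef=coef, residuals=residuals,
                       cis_r=cis_correlation(genes, min_pairs))


# ---------------------------------------------------------------------------
# In-trans rankings
# ---------------------------------------------------------------------------

@dataclass
class TransRanking:
    """Full gene ranking by correlation with one pivot's expression.

    Genes are ordered by descending Pearson correlation between the pivot's
    observed log expression and each gene's residual expression; ties break
    by gene symbol.  Genes with undefined correlation (zero-variance
    residuals) are placed mid-list with correlation 0.
    """

    pivot: str
    genes: list[str]
    correlations: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.genes, "trans_r": self.correlations})


def trans_ranking(pivot: str, expr: pd.DataFrame, residuals: pd.DataFrame,
                  exclude_self: bool = False,
                  min_pairs: int = DEFAULT_MIN_PAIRS) -> TransRanking:
    """Rank all genes by correlation of their residuals with the pivot's
    observed expression (descending)."""
    if pivot not in expr.index:
        raise KeyError(f"pivot gene {pivot!r} not in expression matrix")
    e = expr.loc[pivot].to_numpy(dtype=float)
    R = residuals.to_numpy(dtype=float)
    r = _rowwise_pearson(R, np.broadcast_to(e, R.shape), min_pairs)
    n_undef = int(np.isnan(r).sum())
    if n_undef:
        logger.warning("pivot %s: %d genes with undefined in-trans correlation "
                       "set to 0", pivot, n_undef)
        r = np.nan_to_num(r, nan=0.0)
    names = residuals.index.to_numpy()
    if exclude_self:
        keep = names != pivot
        names, r = names[keep], r[keep]
    order = np.lexsort((names, -r))
    return TransRanking(pivot=pivot, genes=[str(g) for g in names[order]],
                        correlations=r[order])
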