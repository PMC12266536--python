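"""Covariate-adjusted differential expression versus healthy controls.

Per gene, ordinary least squares on log2 expression with an intercept, a
group indicator, and the study covariates (age, sex, one-hot sequencing
batch, RIN).  The group coefficient is the log2 fold change; two-sided
p-values come from the t distribution at the residual degrees of freedom and
are BH-corrected across genes.  Plain OLS is deterministic and sufficient
here; no empirical-Bayes variance moderation is applied.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_fdr

__all__ = ["fit_dge", "deg_sets", "lfc_filter"]

DEFAULT_COVARIATES = ("age", "sex", "batch", "rin")
LFC_THRESHOLD = 0.58   # |log2FC| > 0.58, i.e. ~1.5-fold


def _design(meta: pd.DataFrame, group_mask: np.ndarray, covariates) -> pd.DataFrame:
    cols = {"intercept": np.ones(len(meta)), "group": group_mask.astype(float)}
    X = pd.DataFrame(cols, index=meta.index)
    for cov in covariates:
        v = meta[cov]
        if v.dtype == object or isinstance(v.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(v, prefix=cov, drop_first=True, dtype=float)
            X = pd.concat([X, dummies], axis=1)
        else:
            X[cov] = v.astype(float)
    return X


def fit_dge(expr: pd.DataFrame, meta: pd.DataFrame, group: str,
            reference: str = "HC", covariates=DEFAULT_COVARIATES,
            group_col: str = "cohort", fdr: float = 0.05,
            lfc_threshold: float = LFC_THRESHOLD) -> pd.DataFrame:
    """Per-gene OLS of ``group`` versus ``reference`` samples.

    Samples with missing covariate values are dropped with a warning.
    Returns a DataFrame indexed by gene with columns log2fc, t, p, q,
    passes_fdr, passes_lfc.
    """
    keep = meta[group_col].isin([group, reference])
    sub = meta.loc[keep]
    complete = sub[list(covariates)].notna().all(axis=1)
    if not complete.all():
        dropped = sub.index[~complete].tolist()
        warnings.warn(f"dropping {len(dropped)} sample(s) with missing "
                      f"covariates from DGE: {dropped[:5]}...")
        sub = sub.loc[complete]
    if (sub[group_col] == group).sum() < 2 or (sub[group_col] == reference).sum() < 2:
        raise ValueError("need at least 2 samples per group")

    X = _design(sub, (sub[group_col] == group).to_numpy(), covariates)
    Xv = X.to_numpy(float)
    rank = np.linalg.matrix_rank(Xv)
    if rank < Xv.shape[1]:
        # name the collinear columns: those whose removal restores full rank
        collinear = [c for i, c in enumerate(X.columns)
                     if np.linalg.matrix_rank(np.delete(Xv, i, axis=1)) == rank]
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")

    Y = expr[sub.index].to_numpy(float).T              # samples x genes
    XtX_inv = np.linalg.inv(Xv.T @ Xv)
    beta = XtX_inv @ Xv.T @ Y                          # params x genes
    resid = Y - Xv @ beta
    df_resid = Xv.shape[0] - Xv.shape[1]
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    sigma2 = np.sum(resid ** 2, axis=0) / df_resid
    j = list(X.columns).index("group")
    se = np.sqrt(sigma2 * XtX_inv[j, j])
    log2fc = beta[j]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * sps.t.sf(np.abs(t), df_resid)
    q = bh_fdr(p)
    out = pd.DataFrame({"log2fc": log2fc, "t": t, "p": p, "q": q},
                       index=expr.index)
    out["passes_fdr"] = out["q"] < fdr
    out["passes_lfc"] = out["log2fc"].abs() > lfc_threshold
    return out


def deg_sets(a: pd.DataFrame, b: pd.DataFrame, fdr: float = 0.05) -> dict:
    """Shared / specific DEG sets between two contrasts (by FDR flag)."""
    if set(a.index) != set(b.index):
        raise ValueError("DEG tables cover different gene universes")
    sig_a = set(a.index[a["q"] < fdr])
    sig_b = set(b.index[b["q"] < fdr])
    return {
        "shared": sig_a & sig_b,
        "specific_a": sig_a - sig_b,
        "specific_b": sig_b - sig_a,
        "counts": {"a": len(sig_a), "b": len(sig_b),
                   "shared": len(sig_a & sig_b),
                   "specific_a": len(sig_a - sig_b),
                   "specific_b": len(sig_b - sig_a)},
    }


def lfc_filter(records: pd.DataFrame, threshold: float = LFC_THRESHOLD) -> pd.DataFrame:
    """Strict |log2FC| > threshold subset (0.58 excluded at the boundary)."""
    return records[records["log2fc"].abs() > threshold]
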