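"""Signature-matrix immune-cell deconvolution and the NLR.

Per sample, the un-logged (2^x - 1) marker-gene vector is regressed on the
signature columns by non-negative least squares; coefficients are
renormalized to proportions summing to one (compositional by construction).
The neutrophil-to-lymphocyte ratio divides the neutrophil fraction by the
summed B-, T-, NK- and plasma-cell fractions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .simulate import LYMPHOID_PREFIXES
from .stats import bh_fdr, mann_whitney

__all__ = ["estimate_fractions", "compute_nlr", "compare_fractions"]


def estimate_fractions(expr: pd.DataFrame, signature: pd.DataFrame) -> pd.DataFrame:
    """NNLS cell-fraction estimates per sample.

    Returns samples x (cell types + ``nlr`` + ``residual``); fractions are
    non-negative and sum to 1.  Requires at least half the signature markers
    in the expression matrix; an all-zero sample gets uniform fractions with
    a warning.
    """
    markers = [g for g in signature.index if g in expr.index]
    if len(markers) < 0.5 * len(signature.index):
        raise ValueError(
            f"only {len(markers)}/{len(signature.index)} signature markers "
            "present in the expression matrix")
    S = signature.loc[markers].to_numpy(float)
    X = np.power(2.0, expr.loc[markers].to_numpy(float)) - 1.0   # linear scale
    n_types = S.shape[1]
    rows = []
    for j, sid in enumerate(expr.columns):
        y = X[:, j]
        if not np.any(y > 0):
            warnings.warn(f"all-zero expression for sample {sid!r}; "
                          "returning uniform fractions")
            frac, resid = np.full(n_types, 1.0 / n_types), np.nan
        else:
            coef, resid = nnls(S, y)
            total = coef.sum()
            frac = coef / total if total > 0 else np.full(n_types, 1.0 / n_types)
        rows.append([*frac, resid])
    out = pd.DataFrame(rows, index=expr.columns,
                       columns=[*signature.columns, "residual"])
    out["nlr"] = out.apply(lambda r: compute_nlr(r, signature.columns), axis=1)
    return out


def compute_nlr(fractions: pd.Series, cell_types=None) -> float:
    """Neutrophil fraction over summed lymphoid (B/T/NK/plasma) fractions.

    Zero lymphoid total with non-zero neutrophils is reported as inf.
    """
    if cell_types is None:
        cell_types = [c for c in fractions.index
                      if c not in ("nlr", "residual")]
    lymphoid = [c for c in cell_types if str(c).startswith(LYMPHOID_PREFIXES)]
    neut = float(fractions.get("Neutrophils", 0.0))
    lym = float(sum(fractions[c] for c in lymphoid))
    if lym == 0:
        return 0.0 if neut == 0 else float("inf")
    return neut / lym


def compare_fractions(fractions: pd.DataFrame, groups: pd.Series,
                      cell_types=None) -> pd.DataFrame:
    """Pairwise Mann-Whitney per cell type, BH across cell types per pair.

    ``groups`` maps sample id -> group label; the direction column reports
    the sign of the first-group-minus-second-group median difference.
    """
    groups = groups.loc[fractions.index]
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    if cell_types is None:
        cell_types = [c for c in fractions.columns
                      if c not in ("nlr", "residual")]
    rows = []
    for i, ga in enumerate(levels):
        for gb in levels[i + 1:]:
            pvals = []
            sub = []
            for ct in cell_types:
                x = fractions.loc[groups == ga, ct].to_numpy()
                y = fractions.loc[groups == gb, ct].to_numpy()
                res = mann_whitney(x, y)
                diff = float(np.median(x) - np.median(y))
                sub.append({"group_a": ga, "group_b": gb, "cell_type": ct,
                            "median_a": float(np.median(x)),
                            "median_b": float(np.median(y)),
                            "direction": int(np.sign(diff)),
                            "U": res.statistic, "p": res.p_value})
                pvals.append(res.p_value)
            q = bh_fdr(pvals)
            for r, qv in zip(sub, q):
                r["q"] = qv
            rows.extend(sub)
    return pd.DataFrame(rows)
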