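"""Associations between module dysregulation scores and serology.

Continuous markers are tested with Spearman rank correlation per module x
marker pair; binary statuses (autoantibody positivity, low complement) with
Mann-Whitney on the module z-scores.  Significance is flagged at the
uncorrected p < 0.05 level, mirroring small-cohort serology reporting; a
BH-corrected q column is additionally emitted for users who want it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import bh_fdr, mann_whitney, spearman

__all__ = ["correlate_modules_markers", "modules_by_status"]

MIN_PAIRED = 5


def correlate_modules_markers(d: pd.DataFrame, meta: pd.DataFrame,
                              markers) -> pd.DataFrame:
    """Spearman rho per module x marker, pairwise deletion of missing values."""
    rows = []
    for marker in markers:
        levels = meta.loc[d.index, marker]
        for module in d.columns:
            paired = pd.concat([d[module], levels], axis=1).dropna()
            n = len(paired)
            row = {"module": module, "marker": marker, "kind": "spearman",
                   "n": n}
            if n < MIN_PAIRED:
                row.update({"effect": np.nan, "p": np.nan,
                            "note": "too few paired observations"})
            elif paired.iloc[:, 1].nunique() == 1 or paired.iloc[:, 0].nunique() == 1:
                row.update({"effect": np.nan, "p": np.nan,
                            "note": "constant input, not computable"})
            else:
                res = spearman(paired.iloc[:, 0].to_numpy(),
                               paired.iloc[:, 1].to_numpy())
                row.update({"effect": res.statistic, "p": res.p_value,
                            "note": res.note})
            rows.append(row)
    out = pd.DataFrame(rows)
    out["significant"] = out["p"] < 0.05
    out["direction"] = np.sign(out["effect"]).fillna(0).astype(int)
    ok = out["p"].notna()
    out.loc[ok, "q"] = bh_fdr(out.loc[ok, "p"].to_numpy())
    return out


def modules_by_status(d: pd.DataFrame, meta: pd.DataFrame,
                      status: str) -> pd.DataFrame:
    """Mann-Whitney of module z by a binary status column.

    Direction is the sign of (median positive - median negative).
    """
    s = meta.loc[d.index, status].dropna().astype(bool)
    pos = s.index[s]
    neg = s.index[~s]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError(f"status {status!r} defines a one-group comparison "
                         f"({len(pos)} positive, {len(neg)} negative)")
    rows = []
    for module in d.columns:
        x = d.loc[pos, module].dropna().to_numpy()
        y = d.loc[neg, module].dropna().to_numpy()
        res = mann_whitney(x, y)
        diff = float(np.median(x) - np.median(y))
        rows.append({"module": module, "status": status, "kind": "mannwhitney",
                     "effect": diff, "direction": int(np.sign(diff)),
                     "U": res.statistic, "p": res.p_value,
                     "n_pos": len(x), "n_neg": len(y)})
    out = pd.DataFrame(rows)
    out["significant"] = out["p"] < 0.05
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out
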