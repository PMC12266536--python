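"""Hypergeometric over-representation analysis against GMT collections.

For a query gene list drawn from a background of N genes, each term of size
K (after intersection with the background) is tested with the upper-tail
hypergeometric probability P(X >= k) of observing k overlapping genes in a
query of size n; q-values are BH across all tested terms.  The gene ratio
follows the overlap / term-size convention (k / K).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_fdr

__all__ = ["run_ora"]


def run_ora(query, background, collection: dict,
            min_size: int = 5, max_size: int = 2000):
    """Test every term of ``collection`` for enrichment in ``query``.

    Returns ``(table, skipped)``: a DataFrame sorted by p with columns
    term, k, K, n, N, gene_ratio, p, q, genes; and the list of terms skipped
    for being outside the [min_size, max_size] band after background
    intersection.
    """
    query = set(query)
    background = set(background)
    if not query or not background:
        raise ValueError("query and background must be non-empty")
    if not query <= background:
        raise ValueError("query genes must be a subset of the background")
    N, n = len(background), len(query)
    rows, skipped = [], []
    for term, genes in collection.items():
        members = set(genes) & background
        K = len(members)
        if K < min_size or K > max_size:
            skipped.append(term)
            continue
        overlap = sorted(members & query)
        k = len(overlap)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N,
                     "gene_ratio": k / K, "p": p,
                     "genes": ",".join(overlap)})
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = bh_fdr(table["p"].to_numpy())
        table = table.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        table["q"] = np.nan
    return table, skipped
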