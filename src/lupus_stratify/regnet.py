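"""Regulator enrichment (recovery-curve NES) and drug-response calling.

Genes are ranked by descending |mean z| within a subgroup; for each TF
regulon, a step recovery curve counts cumulative target hits over the top
``top_fraction`` of the ranking, and its area (normalized by window size x
regulon size) gives an AUC in [0, 1].  The normalized enrichment score
standardizes AUCs across all regulons (mean 0, SD 1); the chief regulator is
the top NES.  The conventional NES >= 3 notability bar is reported, not
enforced.

The anticipated-response (reversal) score of drug d for patient p is

    R_pd = mean over targets g of s_g * z_pg,

with s_g = +1 for an inhibited and -1 for a stimulated target: inhibiting an
overexpressed gene, or stimulating an underexpressed one, scores positive.
A patient is called to benefit when R_pd >= tau (default 0.5, requiring the
targets to be meaningfully dysregulated rather than merely positive).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .stats import ContingencyTable2x2, select_categorical_test

__all__ = [
    "rank_genes", "recovery_auc", "nes_scores",
    "response_score", "response_table", "compare_benefit",
]

NES_NOTABILITY = 3.0
DEFAULT_TOP_FRACTION = 0.03
DEFAULT_TAU = 0.5


def rank_genes(z: pd.Series) -> list:
    """Genes by descending |z|, stable tie-break by gene id."""
    if not np.all(np.isfinite(z.to_numpy(float))):
        raise ValueError("non-finite z values")
    order = sorted(z.index, key=lambda g: (-abs(float(z[g])), str(g)))
    return order


def recovery_auc(ranked, targets, top_fraction: float = DEFAULT_TOP_FRACTION) -> float:
    """Area under the target-recovery step curve over the top window.

    The window spans ranks 1..ceil(top_fraction * N); the cumulative hit
    count at each rank is summed and normalized by window size x |targets|.
    """
    targets = set(targets)
    if not targets:
        raise ValueError("empty target set")
    if not targets <= set(ranked):
        raise ValueError("targets outside the ranked universe")
    window = max(1, math.ceil(top_fraction * len(ranked)))
    hits = 0
    area = 0
    for g in ranked[:window]:
        if g in targets:
            hits += 1
        area += hits
    return area / (window * len(targets))


def nes_scores(ranked, regulons: dict,
               top_fraction: float = DEFAULT_TOP_FRACTION) -> pd.DataFrame:
    """Standardized recovery AUC per regulon, sorted descending.

    Requires >= 5 regulons and a non-degenerate AUC spread.
    """
    if len(regulons) < 5:
        raise ValueError("need at least 5 regulons for NES standardization")
    universe = set(ranked)
    rows = []
    for tf, targets in regulons.items():
        members = [g for g in targets if g in universe]
        if not members:
            continue
        rows.append({"tf": tf, "regulon_size": len(members),
                     "auc": recovery_auc(ranked, members, top_fraction)})
    table = pd.DataFrame(rows)
    sd = table["auc"].std(ddof=0)
    if sd == 0:
        raise ValueError("all regulon AUCs identical: uninformative regulon set")
    table["nes"] = (table["auc"] - table["auc"].mean()) / sd
    table = table.sort_values(["nes", "tf"], ascending=[False, True],
                              kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table["notable"] = table["nes"] >= NES_NOTABILITY
    return table


def response_score(z: pd.Series, drug_rows: pd.DataFrame) -> float:
    """Mean signed target z for one patient and one drug (NaN if no target)."""
    signs = drug_rows["action"].map({"inhibits": 1.0, "stimulates": -1.0})
    vals = []
    for g, s in zip(drug_rows["gene"], signs):
        if g in z.index and np.isfinite(z[g]):
            vals.append(s * float(z[g]))
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def response_table(gene_z: pd.DataFrame, drug_targets: pd.DataFrame,
                   tau: float = DEFAULT_TAU) -> pd.DataFrame:
    """Patient x drug reversal scores and benefit calls (R >= tau).

    ``gene_z`` is genes x patients.  Returns a long table with columns
    patient, drug, score, benefit.
    """
    rows = []
    for drug, sub in drug_targets.groupby("drug"):
        for pid in gene_z.columns:
            r = response_score(gene_z[pid], sub)
            rows.append({"patient": pid, "drug": drug, "score": r,
                         "benefit": bool(r >= tau) if np.isfinite(r) else None})
    return pd.DataFrame(rows)


def compare_benefit(calls: pd.DataFrame, assignment) -> pd.DataFrame:
    """Per-drug benefit proportions by subgroup and the categorical test.

    Uses the expected-count policy (Fisher when any expected cell < 5, else
    continuity-corrected chi-squared).
    """
    labels = assignment.labels if hasattr(assignment, "labels") else assignment
    g1 = set(labels.index[labels == 1])
    g2 = set(labels.index[labels == 2])
    if not g1 or not g2:
        raise ValueError("both subgroups must be non-empty")
    rows = []
    for drug, sub in calls.groupby("drug"):
        sub = sub[sub["benefit"].notna()]
        in1 = sub[sub["patient"].isin(g1)]
        in2 = sub[sub["patient"].isin(g2)]
        a = int(in1["benefit"].sum())
        b = len(in1) - a
        c = int(in2["benefit"].sum())
        dd = len(in2) - c
        res = select_categorical_test(ContingencyTable2x2(a, b, c, dd),
                                      policy="expected_lt5_fisher")
        rows.append({"drug": drug,
                     "benefit1": a, "n1": len(in1),
                     "benefit2": c, "n2": len(in2),
                     "prop1": a / len(in1) if len(in1) else np.nan,
                     "prop2": c / len(in2) if len(in2) else np.nan,
                     "p": res.p_value, "method": res.method})
    return pd.DataFrame(rows).sort_values("drug").reset_index(drop=True)
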