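"""Matched controls, module dysregulation z-scores, patient stratification.

Each patient is assigned the ``ratio`` same-sex healthy controls with the
smallest absolute age difference, greedily in ascending patient-id order and
without replacement (ties broken by control id), pooling into a single
reference set (130 controls for 26 patients at 1:5).  Per-gene z-scores are
standardized against the pooled reference mean and SD (n-1 denominator);
the module dysregulation score is the unweighted mean of member-gene
z-scores.  Patients are stratified by Ward clustering on their module
z-vectors; subgroup 1 is, by convention, the cluster with the higher mean
interferon-module z, and subgroup 2 is re-cut into two nested subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .stats import ContingencyTable2x2, mann_whitney, select_categorical_test

__all__ = [
    "MatchAssignment", "SubgroupAssignment",
    "match_controls", "gene_z", "module_z",
    "cluster_patients", "characterize_subgroups",
]


@dataclass
class MatchAssignment:
    mapping: dict                 # patient id -> list of control ids
    pooled: list                  # all selected control ids

    def __post_init__(self) -> None:
        if len(self.pooled) != len(set(self.pooled)):
            raise ValueError("controls reused across patients")


@dataclass
class SubgroupAssignment:
    labels: pd.Series             # patient -> 1 or 2
    nested: pd.Series             # subgroup-2 patient -> "2a" / "2b"
    linkage: np.ndarray | None = None
    anchor_module: str | None = None

    @property
    def sizes(self) -> dict:
        return self.labels.value_counts().to_dict()


def match_controls(patients: pd.DataFrame, hc_pool: pd.DataFrame,
                   ratio: int = 5) -> MatchAssignment:
    """Greedy nearest-age same-sex matching without replacement.

    ``patients`` and ``hc_pool`` are metadata frames indexed by sample id
    with ``age`` and ``sex`` columns.  Deterministic: patients in ascending
    id order; age ties among controls broken by control id order.
    """
    available = hc_pool.sort_index()
    mapping = {}
    taken = set()
    for pid in sorted(patients.index):
        prow = patients.loc[pid]
        cand = available[(available["sex"] == prow["sex"])
                         & (~available.index.isin(taken))]
        if len(cand) < ratio:
            raise ValueError(f"control pool exhausted for patient {pid!r}: "
                             f"{len(cand)} same-sex controls left, need {ratio}")
        order = (cand["age"] - prow["age"]).abs().sort_values(kind="stable")
        chosen = list(order.index[:ratio])
        mapping[pid] = chosen
        taken.update(chosen)
    pooled = [c for pid in sorted(mapping) for c in mapping[pid]]
    return MatchAssignment(mapping=mapping, pooled=pooled)


def gene_z(expr: pd.DataFrame, reference_ids, patient_ids) -> pd.DataFrame:
    """Per-gene z of each patient against the pooled reference (n-1 SD).

    Genes with zero reference SD are excluded with a warning.
    """
    ref = expr[list(reference_ids)]
    if ref.shape[1] < 2:
        raise ValueError("need at least 2 reference samples")
    mu = ref.mean(axis=1)
    sigma = ref.std(axis=1, ddof=1)
    bad = sigma == 0
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} gene(s) with constant "
                      "reference expression")
    keep = ~bad
    z = expr.loc[keep, list(patient_ids)].sub(mu[keep], axis=0).div(
        sigma[keep], axis=0)
    return z


def module_z(gz: pd.DataFrame, modules) -> pd.DataFrame:
    """Patients x modules dysregulation: mean member-gene z (unweighted)."""
    module_map = modules.modules if hasattr(modules, "modules") else modules
    cols = {}
    for label, genes in module_map.items():
        present = [g for g in genes if g in gz.index]
        if not present:
            warnings.warn(f"module {label!r} has no measured genes; dropped")
            continue
        cols[label] = gz.loc[present].mean(axis=0)
    return pd.DataFrame(cols)


def cluster_patients(d: pd.DataFrame, k: int = 2,
                     anchor_module: str | None = None,
                     anchor_scores: pd.Series | None = None) -> SubgroupAssignment:
    """Ward clustering of patients on module z-vectors, cut at k.

    Subgroups are renumbered so subgroup 1 has the higher mean interferon
    dysregulation: either the mean of ``anchor_scores`` (an explicit
    per-patient interferon z, robust when detected modules mix up- and
    down-regulated genes) or the mean z of ``anchor_module`` (default: the
    first column whose name contains "interferon", else the first module).
    For k = 2 the second subgroup is re-cut into nested subsets 2a/2b when
    it has >= 2 patients.
    """
    if d.shape[0] < k:
        raise ValueError(f"k={k} exceeds the {d.shape[0]} patients")
    if d.shape[1] < 1:
        raise ValueError("need at least one module")
    if anchor_module is None:
        ifn = [c for c in d.columns if "interferon" in str(c).lower()]
        anchor_module = ifn[0] if ifn else d.columns[0]
    anchor = (anchor_scores.loc[d.index] if anchor_scores is not None
              else d[anchor_module])
    if k == 1:
        labels = pd.Series(1, index=d.index)
        return SubgroupAssignment(labels=labels,
                                  nested=pd.Series(dtype=object),
                                  anchor_module=anchor_module)
    Z = linkage(d.to_numpy(float), method="ward")
    flat = fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(flat, index=d.index)
    # orientation: subgroup 1 = higher mean anchor z
    means = anchor.groupby(labels).mean().sort_values(ascending=False)
    relabel = {old: new for new, old in enumerate(means.index, start=1)}
    labels = labels.map(relabel)

    nested = pd.Series(dtype=object)
    sub2 = labels.index[labels == 2]
    if k == 2 and len(sub2) >= 2:
        Z2 = linkage(d.loc[sub2].to_numpy(float), method="ward")
        flat2 = fcluster(Z2, t=2, criterion="maxclust")
        nested = pd.Series([f"2{'ab'[c - 1]}" for c in flat2], index=sub2)
    return SubgroupAssignment(labels=labels, nested=nested, linkage=Z,
                              anchor_module=anchor_module)


def characterize_subgroups(assignment: SubgroupAssignment, meta: pd.DataFrame,
                           categorical=(), continuous=(),
                           policy: str = "always_yates") -> pd.DataFrame:
    """Per-variable subgroup comparison table.

    Categorical variables get counts/percentages and the continuity-
    corrected chi-squared (table convention); continuous variables get
    Mann-Whitney.  Missing values are excluded per variable, with the
    per-variable N reported.
    """
    g1 = assignment.labels.index[assignment.labels == 1]
    g2 = assignment.labels.index[assignment.labels == 2]
    rows = []
    for var in categorical:
        if var not in meta.columns:
            continue
        v1 = meta.loc[g1, var].dropna().astype(bool)
        v2 = meta.loc[g2, var].dropna().astype(bool)
        if len(v1) == 0 and len(v2) == 0:
            continue
        a, b = int(v1.sum()), int(len(v1) - v1.sum())
        c, dd = int(v2.sum()), int(len(v2) - v2.sum())
        res = select_categorical_test(ContingencyTable2x2(a, b, c, dd), policy)
        rows.append({"variable": var, "kind": "categorical",
                     "n1": len(v1), "n2": len(v2),
                     "pos1": a, "pos2": c,
                     "pct1": 100.0 * a / len(v1) if len(v1) else np.nan,
                     "pct2": 100.0 * c / len(v2) if len(v2) else np.nan,
                     "statistic": res.statistic, "p": res.p_value,
                     "method": res.method})
    for var in continuous:
        if var not in meta.columns:
            continue
        v1 = meta.loc[g1, var].dropna().astype(float)
        v2 = meta.loc[g2, var].dropna().astype(float)
        if len(v1) == 0 or len(v2) == 0:
            continue
        res = mann_whitney(v1.to_numpy(), v2.to_numpy())
        rows.append({"variable": var, "kind": "continuous",
                     "n1": len(v1), "n2": len(v2),
                     "median1": float(v1.median()), "median2": float(v2.median()),
                     "statistic": res.statistic, "p": res.p_value,
                     "method": res.method})
    return pd.DataFrame(rows)
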