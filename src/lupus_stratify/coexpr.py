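"""Co-expression module discovery (WGCNA core).

Adjacency is |cor|^beta (unsigned, the default) or ((1+cor)/2)^beta
(signed); the soft power beta is the smallest with a scale-free topology fit
R^2 above the target.  Topological overlap

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with connectivity k_i = sum_{u != i} a_iu, measures shared-neighbour
similarity; genes are clustered by average linkage on 1 - TOM.  Modules are
cut at a static height (0.99 quantile of the merge heights) and branches
below the minimum size fall into an unassigned bucket — a deterministic
simplification of dynamic tree cutting.  The module eigengene is the first
principal component of the standardized member expression, oriented so its
correlation with the mean member expression is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .stats import bh_fdr

__all__ = [
    "CoexpressionParams", "ModuleSet",
    "adjacency", "pick_soft_threshold", "compute_tom",
    "detect_modules", "replicate_modules", "cluster_modules",
]


@dataclass
class CoexpressionParams:
    beta: int
    scale_free_r2: float
    signed: bool = False
    r2_by_power: dict = field(default_factory=dict)
    min_module_size: int = 30


@dataclass
class ModuleSet:
    """Named gene modules with eigengenes and meta-cluster annotation."""

    modules: dict                      # label -> gene list
    eigengenes: pd.DataFrame           # samples x modules, unit variance
    linkage: np.ndarray | None = None  # gene dendrogram
    unassigned: list = field(default_factory=list)
    annotation: dict = field(default_factory=dict)  # label -> cluster name
    cut_height: float | None = None

    def __post_init__(self) -> None:
        all_genes = [g for m in self.modules.values() for g in m]
        if len(all_genes) != len(set(all_genes)):
            raise ValueError("modules must be disjoint")

    @property
    def labels(self) -> list:
        return list(self.modules)


def adjacency(expr: pd.DataFrame, beta: int, signed: bool = False) -> pd.DataFrame:
    """Soft-thresholded co-expression adjacency (genes x genes)."""
    X = expr.to_numpy(float)
    with np.errstate(invalid="ignore"):
        cor = np.corrcoef(X)
    cor = np.nan_to_num(cor, nan=0.0)
    a = ((1.0 + cor) / 2.0) ** beta if signed else np.abs(cor) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def _scale_free_r2(k: np.ndarray, nbins: int = 10) -> float:
    """Fit of log10 p(k) vs log10 k over connectivity histogram bins."""
    k = k[k > 0]
    if k.size < 2 or np.allclose(k, k[0]):
        return 0.0
    counts, edges = np.histogram(k, bins=nbins)
    centers = np.array([k[(k >= edges[i]) & (k <= edges[i + 1])].mean()
                        if counts[i] else np.nan for i in range(nbins)])
    keep = (counts > 0) & (centers > 0)
    if keep.sum() < 3:
        return 0.0
    logk = np.log10(centers[keep])
    logp = np.log10(counts[keep] / counts.sum())
    if np.allclose(logk, logk[0]) or np.allclose(logp, logp[0]):
        return 0.0
    return float(np.corrcoef(logk, logp)[0, 1] ** 2)


def pick_soft_threshold(expr: pd.DataFrame, powers=range(1, 21),
                        target_r2: float = 0.8,
                        signed: bool = False) -> CoexpressionParams:
    """Smallest soft power with scale-free fit R^2 >= target.

    Falls back to the argmax power (with a warning) when no candidate
    reaches the target.
    """
    if expr.shape[1] < 8:
        raise ValueError("need at least 8 samples for stable correlations")
    r2 = {}
    for beta in powers:
        a = adjacency(expr, beta, signed=signed).to_numpy()
        np.fill_diagonal(a, 0.0)
        r2[beta] = _scale_free_r2(a.sum(axis=0))
    for beta in powers:
        if r2[beta] >= target_r2:
            return CoexpressionParams(beta=beta, scale_free_r2=r2[beta],
                                      signed=signed, r2_by_power=r2)
    best = max(r2, key=r2.get)
    warnings.warn(f"no power reached scale-free R^2 {target_r2}; "
                  f"using argmax beta={best} (R^2={r2[best]:.3f})")
    return CoexpressionParams(beta=best, scale_free_r2=r2[best],
                              signed=signed, r2_by_power=r2)


def compute_tom(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix; diagonal 1, entries in [0, 1]."""
    a = adj.to_numpy(float).copy()
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=0)
    num = a @ a + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = np.where(denom > 0, num / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def _eigengene(expr_members: pd.DataFrame) -> pd.Series:
    """First PC of standardized member expression, positively oriented."""
    X = expr_members.to_numpy(float)                     # genes x samples
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = ((X - mu) / sd).T                                # samples x genes
    u, s, _ = np.linalg.svd(Z - Z.mean(axis=0), full_matrices=False)
    scores = u[:, 0] * s[0]
    sd_scores = scores.std(ddof=1)
    if sd_scores > 0:
        scores = scores / sd_scores
    mean_expr = Z.mean(axis=1)
    if np.corrcoef(scores, mean_expr)[0, 1] < 0:
        scores = -scores
    return pd.Series(scores, index=expr_members.columns)


def detect_modules(tom: pd.DataFrame, expr: pd.DataFrame,
                   min_module_size: int = 30,
                   cut_height: float = 0.99,
                   kme_min: float = 0.5,
                   merge_cor: float = 0.8,
                   max_refine: int = 4) -> ModuleSet:
    """Cut the average-linkage gene dendrogram on 1 - TOM into modules.

    The static cut height is chosen from the tree itself: among candidate
    heights (quantiles of the merge heights, capped at ``cut_height``) the
    one producing the most branches of at least ``min_module_size`` genes
    wins, ties going to the lower height.  Merge heights on a 1 - TOM
    dendrogram depend on the network scale (unconnected genes aggregate
    near 1, but how near depends on the noise connectivity), so a fixed
    absolute cut does not transfer across gene-universe sizes; the scan is
    deterministic and scale-free.  Branches below the cut that miss the
    minimum size fall into the unassigned bucket.  The candidate modules
    are then refined by the standard eigengene post-processing — modules
    whose eigengenes correlate above ``merge_cor`` are merged, and every
    gene is re-assigned to the module of its best-correlated eigengene when
    that module membership correlation (kME) reaches ``kme_min`` — iterated
    to a fixed point (at most ``max_refine`` rounds; deterministic
    throughout).
    """
    genes = list(tom.index)
    d = 1.0 - tom.to_numpy(float)
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method="average")
    heights = Z[:, 2]
    candidates = np.unique(np.concatenate([
        np.quantile(heights, np.linspace(0.5, 0.999, 40)),
        [min(cut_height, float(heights.max()))]]))
    candidates = candidates[candidates <= min(cut_height, float(heights.max()))]
    best_cut, best_n, flat = float(candidates[0]), -1, None
    for cand in candidates:
        f = fcluster(Z, t=float(cand), criterion="distance")
        n_kept = int((pd.Series(f).value_counts() >= min_module_size).sum())
        if n_kept > best_n:
            best_cut, best_n, flat = float(cand), n_kept, f
    cut = best_cut

    sizes = pd.Series(flat).value_counts()
    mods = {cid: [genes[i] for i in np.flatnonzero(flat == cid)]
            for cid in sizes.index[sizes >= min_module_size]}
    mods = _refine_modules(mods, expr, min_module_size, kme_min, merge_cor,
                           max_refine)
    if not mods:
        warnings.warn("all genes unassigned: no branch reached the minimum "
                      "module size")
        return ModuleSet(modules={}, eigengenes=pd.DataFrame(index=expr.columns),
                         linkage=Z, unassigned=sorted(genes), cut_height=cut)
    kept = sorted(mods.values(), key=lambda m: (-len(m), m[0]))
    modules = {f"M{i + 1:02d}": sorted(members) for i, members in enumerate(kept)}
    assigned = {g for m in modules.values() for g in m}
    unassigned = sorted(set(genes) - assigned)
    eig = pd.DataFrame({lab: _eigengene(expr.loc[members])
                        for lab, members in modules.items()})
    return ModuleSet(modules=modules, eigengenes=eig, linkage=Z,
                     unassigned=unassigned, cut_height=cut)


def _refine_modules(mods: dict, expr: pd.DataFrame, min_module_size: int,
                    kme_min: float, merge_cor: float, max_refine: int) -> dict:
    """Eigengene merge + kME re-assignment to a fixed point."""
    if not mods:
        return {}
    genes = list(expr.index)
    X = expr.to_numpy(float)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=1, keepdims=True)) / sd
    Es = pd.DataFrame(Xs, index=expr.index, columns=expr.columns)
    for _ in range(max_refine):
        eig = {cid: _eigengene(Es.loc[mem]).to_numpy()
               for cid, mem in mods.items()}
        labels = list(eig)
        EG = np.array([eig[c] for c in labels])
        if len(labels) > 1:
            C = np.corrcoef(EG)
            merged = False
            for i in range(len(labels)):
                for j in range(i + 1, len(labels)):
                    if (C[i, j] >= merge_cor and labels[i] in mods
                            and labels[j] in mods):
                        mods[labels[i]] = mods[labels[i]] + mods.pop(labels[j])
                        merged = True
            if merged:
                continue
        kme = np.corrcoef(np.vstack([Xs, EG]))[:len(genes), len(genes):]
        best = np.argmax(kme, axis=1)
        best_v = kme[np.arange(len(genes)), best]
        new = {c: [] for c in labels}
        for gi, g in enumerate(genes):
            if best_v[gi] >= kme_min:
                new[labels[best[gi]]].append(g)
        new = {c: m for c, m in new.items() if len(m) >= min_module_size}
        if ({c: sorted(m) for c, m in new.items()}
                == {c: sorted(m) for c, m in mods.items()}):
            break
        mods = new
        if not mods:
            break
    return mods


def replicate_modules(a: ModuleSet, b: ModuleSet, universe) -> pd.DataFrame:
    """Cross-cohort module overlap table (hypergeometric, BH-corrected).

    A module of ``a`` is replicated in ``b`` when its best-overlap partner
    has q < 0.05 and the overlap covers >= 30% of the smaller module.
    """
    universe = set(universe)
    N = len(universe)
    rows = []
    for la, ga in a.modules.items():
        sa = set(ga) & universe
        for lb, gb in b.modules.items():
            sb = set(gb) & universe
            k = len(sa & sb)
            p = float(sps.hypergeom.sf(k - 1, N, len(sb), len(sa)))
            frac = k / min(len(sa), len(sb)) if min(len(sa), len(sb)) else 0.0
            rows.append({"module_a": la, "module_b": lb, "overlap": k,
                         "size_a": len(sa), "size_b": len(sb),
                         "overlap_frac": frac, "p": p})
    table = pd.DataFrame(rows)
    if not len(table):
        return table
    table["q"] = bh_fdr(table["p"].to_numpy())
    table["replicated"] = (table["q"] < 0.05) & (table["overlap_frac"] >= 0.30)
    return table


def cluster_modules(module_set: ModuleSet, k: int = 5,
                    annotation_sets: dict | None = None,
                    universe=None) -> dict:
    """Ward meta-clustering of eigengenes into k clusters, with labels.

    Distance is 1 - Pearson correlation of eigengenes.  Cluster labels come
    from the annotation signature set with the smallest hypergeometric
    overlap p against the cluster's pooled member genes (automating the
    manual annotation step); without annotation sets, clusters are labelled
    cluster_1..k.
    """
    labels = module_set.labels
    if k > len(labels):
        raise ValueError(f"k={k} exceeds the {len(labels)} modules")
    eig = module_set.eigengenes[labels]
    d = 1.0 - np.corrcoef(eig.to_numpy().T)
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method="ward")
    flat = fcluster(Z, t=k, criterion="maxclust")

    cluster_names = {}
    if annotation_sets:
        universe = set(universe) if universe is not None else set(
            g for m in module_set.modules.values() for g in m)
        N = len(universe)
        for cid in np.unique(flat):
            pooled = set().union(*(module_set.modules[labels[i]]
                                   for i in np.flatnonzero(flat == cid)))
            pooled &= universe
            best, best_p = None, 1.1
            for name, genes in annotation_sets.items():
                s = set(genes) & universe
                if not s:
                    continue
                kk = len(pooled & s)
                p = float(sps.hypergeom.sf(kk - 1, N, len(s), len(pooled)))
                if p < best_p:
                    best, best_p = name, p
            cluster_names[cid] = (best or f"cluster_{cid}").removeprefix("sig_")
    else:
        cluster_names = {cid: f"cluster_{cid}" for cid in np.unique(flat)}
    annotation = {labels[i]: cluster_names[flat[i]] for i in range(len(labels))}
    module_set.annotation = annotation
    return annotation
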