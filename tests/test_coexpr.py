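"""WGCNA core: adjacency, TOM, module detection, replication, meta-clusters."""

import numpy as np
import pandas as pd
import pytest

from lupus_stratify import coexpr
from lupus_stratify.coexpr import (
    ModuleSet,
    adjacency,
    cluster_modules,
    compute_tom,
    detect_modules,
    pick_soft_threshold,
    replicate_modules,
)


def tom_oracle(a: np.ndarray) -> np.ndarray:
    """Brute-force double-loop topological overlap."""
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=0)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            num = sum(a[i, u] * a[u, j] for u in range(n)) + a[i, j]
            out[i, j] = num / (min(k[i], k[j]) + 1 - a[i, j])
    return out


def two_block_expression(n_samples=26, block=50, within=0.8, seed=0):
    """Two independent blocks with within-block correlation ~`within`."""
    rng = np.random.default_rng(seed)
    lam = np.sqrt(within / (1 - within))
    rows, names = [], []
    for b in range(2):
        latent = rng.normal(size=n_samples)
        for g in range(block):
            rows.append(lam * latent + rng.normal(size=n_samples))
            names.append(f"B{b}_{g:02d}")
    return pd.DataFrame(rows, index=names)


class TestAdjacency:
    def test_power_arithmetic_on_known_correlation(self):
        # construct two genes with correlation exactly 0.5
        v1 = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        v2 = np.array([1.0, 1.0, -1.0, -1.0, 1.0, 1.0, -1.0, -1.0])
        g2 = 0.5 * v1 + np.sqrt(0.75) * v2
        expr = pd.DataFrame([v1, g2], index=["a", "b"])
        a = adjacency(expr, beta=2)
        assert a.loc["a", "b"] == pytest.approx(0.25, abs=1e-12)

    def test_perfect_correlation_fixed_point(self):
        x = np.arange(10.0)
        expr = pd.DataFrame([x, 2 * x + 3], index=["a", "b"])
        for beta in (1, 5, 12):
            assert adjacency(expr, beta).loc["a", "b"] == pytest.approx(1.0)

    def test_signed_mode(self):
        x = np.arange(10.0)
        expr = pd.DataFrame([x, -x], index=["a", "b"])
        assert adjacency(expr, 2, signed=True).loc["a", "b"] == pytest.approx(0.0, abs=1e-12)


class TestTom:
    def test_perfect_overlap(self):
        a = pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=list("abc"))
        tom = compute_tom(a)
        assert np.allclose(tom.to_numpy(), 1.0)

    def test_hand_computed_triangle(self):
        a = np.array([[1.0, 0.5, 0.5], [0.5, 1.0, 0.0], [0.5, 0.0, 1.0]])
        tom = compute_tom(pd.DataFrame(a, index=list("abc"), columns=list("abc")))
        assert tom.loc["b", "c"] == pytest.approx(1 / 6)

    def test_matches_bruteforce_oracle_on_random_networks(self):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            a = rng.random((20, 20))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 1.0)
            df = pd.DataFrame(a)
            assert np.allclose(compute_tom(df).to_numpy(), tom_oracle(a),
                               atol=1e-12)

    def test_asymmetric_input_rejected(self):
        a = np.eye(3)
        a[0, 1] = 0.5
        with pytest.raises(ValueError):
            compute_tom(pd.DataFrame(a))


class TestSoftThreshold:
    def test_too_few_samples_rejected(self):
        expr = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 5)))
        with pytest.raises(ValueError):
            pick_soft_threshold(expr)

    def test_returns_valid_params_on_planted_data(self, cohort):
        meta = cohort.meta
        cns = meta.index[meta["cohort"] == "CNS_LUPUS"]
        params = pick_soft_threshold(cohort.expr[cns])
        assert params.beta >= 1
        assert 0.0 <= params.scale_free_r2 <= 1.0
        assert set(params.r2_by_power) == set(range(1, 21))


class TestDetectModules:
    def test_two_block_recovery(self):
        expr = two_block_expression(seed=1)
        params = coexpr.CoexpressionParams(beta=6, scale_free_r2=np.nan)
        tom = compute_tom(adjacency(expr, params.beta))
        ms = detect_modules(tom, expr, min_module_size=10)
        assert len(ms.labels) == 2
        for block in ("B0", "B1"):
            truth = {g for g in expr.index if g.startswith(block)}
            jac = max(len(truth & set(m)) / len(truth | set(m))
                      for m in ms.modules.values())
            assert jac >= 0.9

    def test_min_size_above_gene_count_leaves_all_unassigned(self):
        expr = two_block_expression(block=10, seed=2)
        tom = compute_tom(adjacency(expr, 6))
        with pytest.warns(UserWarning, match="unassigned"):
            ms = detect_modules(tom, expr, min_module_size=100)
        assert not ms.modules and len(ms.unassigned) == 20

    def test_gene_order_permutation_invariance(self):
        expr = two_block_expression(seed=3)
        tom = compute_tom(adjacency(expr, 6))
        ms1 = detect_modules(tom, expr, min_module_size=10)
        perm = list(expr.index[::-1])
        ms2 = detect_modules(tom.loc[perm, perm], expr.loc[perm],
                             min_module_size=10)
        sets1 = sorted(frozenset(m) for m in ms1.modules.values())
        sets2 = sorted(frozenset(m) for m in ms2.modules.values())
        assert sets1 == sets2

    def test_eigengene_of_identical_vectors(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 0.0])
        expr = pd.DataFrame([x, x, x], index=["a", "b", "c"])
        eig = coexpr._eigengene(expr)
        zx = (x - x.mean()) / x.std()
        scaled = zx / zx.std(ddof=1)
        assert np.allclose(eig.to_numpy(), scaled, atol=1e-9)
        assert np.corrcoef(eig, x)[0, 1] > 0

    def test_eigengene_unit_variance_and_orientation(self, cohort):
        meta = cohort.meta
        cns = meta.index[meta["cohort"] == "CNS_LUPUS"]
        expr = cohort.expr[cns]
        tom = compute_tom(adjacency(expr, 6))
        ms = detect_modules(tom, expr, min_module_size=10)
        for lab in ms.labels:
            eig = ms.eigengenes[lab]
            assert eig.std(ddof=1) == pytest.approx(1.0, rel=1e-6)
            mean_expr = expr.loc[ms.modules[lab]].mean()
            assert np.corrcoef(eig, mean_expr)[0, 1] > 0


class TestReplication:
    def _module_set(self, modules):
        n = 12
        rng = np.random.default_rng(0)
        eig = pd.DataFrame(rng.normal(size=(n, len(modules))),
                           columns=list(modules))
        return ModuleSet(modules=modules, eigengenes=eig)

    def test_identical_sets_fully_replicated(self):
        mods = {"M1": [f"g{i}" for i in range(30)],
                "M2": [f"h{i}" for i in range(30)]}
        ms = self._module_set(mods)
        universe = mods["M1"] + mods["M2"] + [f"x{i}" for i in range(200)]
        table = replicate_modules(ms, ms, universe)
        own = table[table["module_a"] == table["module_b"]]
        assert own["replicated"].all()
        assert (own["overlap_frac"] == 1.0).all()

    def test_disjoint_random_modules_do_not_replicate(self):
        rng = np.random.default_rng(5)
        universe = [f"g{i}" for i in range(2000)]
        hits = 0
        for _ in range(5):
            picks = rng.choice(universe, 60, replace=False)
            a = self._module_set({"A": list(picks[:30])})
            b = self._module_set({"B": list(picks[30:])})
            t = replicate_modules(a, b, universe)
            hits += int(t["replicated"].any())
        assert hits == 0

    def test_split_module_replicates_via_major_partner(self):
        ga = [f"g{i}" for i in range(30)]
        a = self._module_set({"A": ga})
        b = self._module_set({"B1": ga[:18] + ["x1", "x2"],
                              "B2": ga[18:] + ["x3", "x4"]})
        universe = ga + [f"x{i}" for i in range(400)]
        t = replicate_modules(a, b, universe)
        major = t[(t["module_a"] == "A") & (t["module_b"] == "B1")].iloc[0]
        assert major["replicated"]

    def test_empty_module_set_gives_empty_table(self):
        empty = ModuleSet(modules={}, eigengenes=pd.DataFrame())
        full = self._module_set({"A": ["g1"] * 0 + [f"g{i}" for i in range(10)]})
        assert len(replicate_modules(empty, full, [f"g{i}" for i in range(10)])) == 0


class TestClusterModules:
    def _eig_set(self, k_groups=2, per_group=3, n=30, seed=0):
        rng = np.random.default_rng(seed)
        modules, eigs = {}, {}
        for g in range(k_groups):
            latent = rng.normal(size=n)
            for j in range(per_group):
                lab = f"M{g}{j}"
                modules[lab] = [f"g{g}{j}_{i}" for i in range(12)]
                eigs[lab] = 3 * latent + rng.normal(size=n)
        return ModuleSet(modules=modules, eigengenes=pd.DataFrame(eigs))

    def test_k_equals_n_modules_gives_singletons(self):
        ms = self._eig_set()
        ann = cluster_modules(ms, k=6)
        assert len(set(ann.values())) == 6

    def test_planted_supergroups_split_perfectly(self):
        ms = self._eig_set(seed=4)
        ann = cluster_modules(ms, k=2)
        groups = {}
        for lab, cl in ann.items():
            groups.setdefault(cl, set()).add(lab[1])
        assert sorted(groups.values(), key=len) == [{"0"}, {"1"}] or \
            all(len(v) == 1 for v in groups.values())

    def test_k_above_module_count_rejected(self):
        ms = self._eig_set()
        with pytest.raises(ValueError):
            cluster_modules(ms, k=7)

    def test_annotation_labels_planted_ifn_module(self, cohort):
        meta = cohort.meta
        cns = meta.index[meta["cohort"] == "CNS_LUPUS"]
        expr = cohort.expr[cns]
        tom = compute_tom(adjacency(expr, 6))
        ms = detect_modules(tom, expr, min_module_size=10)
        ann_sets = {k: v for k, v in cohort.genesets.items()
                    if k.startswith("sig_")}
        ann = cluster_modules(ms, k=min(5, len(ms.labels)),
                              annotation_sets=ann_sets,
                              universe=cohort.expr.index)
        # the module carrying most planted interferon genes is annotated so
        ifn_truth = set(cohort.modules_truth["interferon"])
        best = max(ms.labels, key=lambda m: len(ifn_truth & set(ms.modules[m])))
        assert ann[best] == "interferon"
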