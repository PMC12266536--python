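"""Matched controls, dysregulation z-scores, patient stratification."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from lupus_stratify import dysreg
from lupus_stratify.dysreg import (
    cluster_patients,
    characterize_subgroups,
    gene_z,
    match_controls,
    module_z,
)


def _meta(records):
    return pd.DataFrame(records).set_index("sample_id")


class TestMatching:
    def test_pool_size_constant(self, cohort, matched):
        match, _ = matched
        assert len(match.pooled) == 26 * 5 == 130
        assert len(set(match.pooled)) == 130
        # same-sex constraint
        for pid, controls in match.mapping.items():
            psex = cohort.meta.loc[pid, "sex"]
            assert (cohort.meta.loc[controls, "sex"] == psex).all()

    def test_exactly_sufficient_pool(self):
        patients = _meta([{"sample_id": "p1", "age": 40.0, "sex": "F"}])
        hc = _meta([{"sample_id": f"h{i}", "age": 30.0 + i, "sex": "F"}
                    for i in range(5)])
        match = match_controls(patients, hc, ratio=5)
        assert sorted(match.mapping["p1"]) == sorted(hc.index)

    def test_matches_bruteforce_oracle_on_small_pools(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            patients = _meta([{"sample_id": f"p{i}", "age": float(rng.uniform(20, 70)),
                               "sex": "F"} for i in range(2)])
            hc = _meta([{"sample_id": f"h{i:02d}", "age": float(rng.uniform(20, 70)),
                         "sex": "F"} for i in range(15)])
            match = match_controls(patients, hc, ratio=3)
            # oracle: greedy in patient id order, stable sort by (|age diff|, id)
            taken = set()
            for pid in sorted(patients.index):
                cands = [(abs(hc.loc[h, "age"] - patients.loc[pid, "age"]), h)
                         for h in hc.index if h not in taken]
                expected = [h for _, h in sorted(cands)[:3]]
                assert match.mapping[pid] == expected
                taken.update(expected)

    def test_pool_exhaustion_names_patient(self):
        patients = _meta([{"sample_id": "p1", "age": 40.0, "sex": "M"}])
        hc = _meta([{"sample_id": "h1", "age": 41.0, "sex": "F"}])
        with pytest.raises(ValueError, match="p1"):
            match_controls(patients, hc, ratio=1)


class TestGeneZ:
    def test_hand_computed_example(self):
        expr = pd.DataFrame({"r1": [1.0], "r2": [2.0], "r3": [3.0],
                             "p1": [4.0]}, index=["g"])
        z = gene_z(expr, ["r1", "r2", "r3"], ["p1"])
        assert z.loc["g", "p1"] == pytest.approx(2.0)  # (4-2)/1, n-1 SD

    def test_reference_value_maps_to_zero_and_one(self):
        expr = pd.DataFrame({"r1": [0.0], "r2": [2.0], "p1": [1.0],
                             "p2": [1.0 + np.sqrt(2)]}, index=["g"])
        z = gene_z(expr, ["r1", "r2"], ["p1", "p2"])
        assert z.loc["g", "p1"] == pytest.approx(0.0)
        assert z.loc["g", "p2"] == pytest.approx(1.0)

    def test_constant_reference_gene_excluded(self):
        expr = pd.DataFrame({"r1": [1.0, 5.0], "r2": [1.0, 6.0],
                             "p1": [3.0, 7.0]}, index=["g1", "g2"])
        with pytest.warns(UserWarning, match="constant"):
            z = gene_z(expr, ["r1", "r2"], ["p1"])
        assert "g1" not in z.index and "g2" in z.index

    def test_pooled_reference_self_standardization(self, cohort, matched):
        # construction identity: the pooled controls evaluated against their
        # own reference have per-gene mean 0 and SD 1
        match, _ = matched
        z_ref = gene_z(cohort.expr, match.pooled, match.pooled)
        assert np.allclose(z_ref.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(z_ref.std(axis=1, ddof=1), 1.0, atol=1e-9)


class TestModuleZ:
    def test_unweighted_mean(self):
        gz = pd.DataFrame({"p1": [1.0, 3.0]}, index=["g1", "g2"])
        d = module_z(gz, {"m": ["g1", "g2"]})
        assert d.loc["p1", "m"] == pytest.approx(2.0)

    def test_zero_gene_z_gives_zero_module_z(self):
        gz = pd.DataFrame(0.0, index=["g1", "g2"], columns=["p1", "p2"])
        d = module_z(gz, {"m": ["g1", "g2"]})
        assert (d.to_numpy() == 0).all()

    def test_unmeasured_module_dropped_with_warning(self):
        gz = pd.DataFrame({"p1": [1.0]}, index=["g1"])
        with pytest.warns(UserWarning, match="dropped"):
            d = module_z(gz, {"m": ["g1"], "ghost": ["zz"]})
        assert list(d.columns) == ["m"]

    def test_planted_ifn_dysregulation_recovered(self, cohort, matched):
        # planted +2.5 SD interferon effect in subgroup 1, attenuated by the
        # shared activity latent: mean z over S1 lands near delta/sqrt(1+s^2)
        _, gz = matched
        d = module_z(gz, cohort.modules_truth)
        meta = cohort.meta
        s1 = [p for p in d.index if meta.loc[p, "planted_subgroup"] == "S1"]
        s2 = [p for p in d.index if meta.loc[p, "planted_subgroup"] == "S2"]
        assert d.loc[s1, "interferon"].mean() > d.loc[s2, "interferon"].mean()
        assert d.loc[s1, "b_cell"].mean() < -1.0


class TestClusterPatients:
    def _planted_d(self, delta=2.0, n1=8, n2=10, seed=0):
        rng = np.random.default_rng(seed)
        cols = ["interferon", "b_cell", "t_cell", "nk"]
        signs = {"interferon": 1, "b_cell": -1, "t_cell": -1, "nk": -1}
        rows = []
        idx = []
        for i in range(n1):
            idx.append(f"p{i:02d}")
            rows.append([signs[c] * delta + 0.3 * rng.normal() for c in cols])
        for i in range(n2):
            idx.append(f"q{i:02d}")
            rows.append([0.3 * rng.normal() for _ in cols])
        return pd.DataFrame(rows, index=idx, columns=cols)

    def test_strong_separation_perfect_recovery(self):
        d = self._planted_d()
        a = cluster_patients(d, k=2)
        truth = [1] * 8 + [2] * 10
        assert adjusted_rand_score(truth, a.labels) == 1.0
        # orientation: subgroup 1 holds the high-interferon patients
        assert set(a.labels.index[a.labels == 1]) == set(d.index[:8])

    def test_k1_trivial_assignment(self):
        d = self._planted_d()
        a = cluster_patients(d, k=1)
        assert (a.labels == 1).all()

    def test_duplicated_patients_co_assigned(self):
        d = self._planted_d()
        d.loc["dup"] = d.loc["p00"]
        a = cluster_patients(d, k=2)
        assert a.labels["dup"] == a.labels["p00"]

    def test_nested_subsets_partition_subgroup2(self):
        d = self._planted_d(seed=2)
        a = cluster_patients(d, k=2)
        sub2 = set(a.labels.index[a.labels == 2])
        assert set(a.nested.index) == sub2
        assert set(a.nested.unique()) <= {"2a", "2b"}

    def test_k_above_patient_count_rejected(self):
        with pytest.raises(ValueError):
            cluster_patients(self._planted_d(n1=1, n2=1), k=5)


class TestCharacterize:
    def _assignment(self, n1=11, n2=15):
        labels = pd.Series([1] * n1 + [2] * n2,
                           index=[f"p{i:02d}" for i in range(n1 + n2)])
        return dysreg.SubgroupAssignment(labels=labels,
                                         nested=pd.Series(dtype=object))

    def test_reproduces_subgroup_table_pvalues(self):
        a = self._assignment()
        meta = pd.DataFrame(index=a.labels.index)
        # haematologic: 4/11 vs 0/15
        meta["haematologic"] = [True] * 4 + [False] * 7 + [False] * 15
        # anti-dsDNA: 4/9 measured vs 0/12 measured
        meta["anti_dsdna_pos"] = ([1.0] * 4 + [0.0] * 5 + [np.nan] * 2
                                  + [0.0] * 12 + [np.nan] * 3)
        table = characterize_subgroups(a, meta,
                                       categorical=["haematologic",
                                                    "anti_dsdna_pos"])
        by_var = table.set_index("variable")
        assert round(by_var.loc["haematologic", "p"], 3) == 0.047
        assert round(by_var.loc["anti_dsdna_pos", "p"], 3) == 0.045
        assert by_var.loc["anti_dsdna_pos", "n1"] == 9
        assert by_var.loc["anti_dsdna_pos", "n2"] == 12

    def test_identical_distributions_give_p_one(self):
        a = self._assignment(5, 5)
        meta = pd.DataFrame({"flag": [True, False] * 5,
                             "level": [1.0, 2.0, 3.0, 4.0, 5.0] * 2},
                            index=a.labels.index)
        table = characterize_subgroups(a, meta, categorical=["flag"],
                                       continuous=["level"])
        assert (table["p"] == 1.0).all()

    def test_absent_variable_skipped(self):
        a = self._assignment(3, 3)
        meta = pd.DataFrame(index=a.labels.index)
        table = characterize_subgroups(a, meta, categorical=["ghost"])
        assert len(table) == 0


class TestRecoveryCurveProperty:
    def test_ari_degrades_as_effect_vanishes(self):
        """Separation is perfect at strong planted effects, lost at zero."""
        from lupus_stratify.simulate import SimulationConfig, simulate_cohort

        from lupus_stratify.simulate import _DEFAULT_EFFECTS

        signs = {m: np.sign(v[0]) for m, v in _DEFAULT_EFFECTS.items()}
        aris = {}
        for delta in (0.0, 1.5):
            scores = []
            for seed in range(3):
                effects = {m: (s * delta, 0.0, 0.0) for m, s in signs.items()}
                cfg = SimulationConfig(n_genes=400, module_size=20, n_hc=160,
                                       module_effects=effects,
                                       cns_deg_delta=0.0, seed=400 + seed)
                co = simulate_cohort(cfg)
                meta = co.meta
                patients = meta[meta["cohort"] == "CNS_LUPUS"]
                match = match_controls(patients, meta[meta["cohort"] == "HC"])
                gz = gene_z(co.expr, match.pooled, list(patients.index))
                d = module_z(gz, co.modules_truth)
                a = cluster_patients(d, k=2)
                scores.append(adjusted_rand_score(
                    meta.loc[patients.index, "planted_subgroup"], a.labels))
            aris[delta] = np.mean(scores)
        assert aris[1.5] > 0.8
        assert aris[0.0] < 0.3
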