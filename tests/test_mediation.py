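import numpy as np
import pandas as pd
import pytest

from micromed import diversity as dv
from micromed import mediation as md
from micromed import synthdata as sd
from micromed.preprocess import zero_replace
from tests.conftest import logistic_normal_z


def bray_dm(x_rel):
    n = x_rel.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        d[i] = np.abs(x_rel[i] - x_rel).sum(1) / (x_rel[i] + x_rel).sum(1)
    np.fill_diagonal(d, 0.0)
    return dv.DistanceMatrix(list(range(n)), d, "bray_curtis")


class TestDistanceMediation:
    @staticmethod
    def _null_with_direct_effect(seed, n=48):
        rng = np.random.default_rng(seed)
        x = np.repeat([0.0, 1.0], n // 2)
        rel = np.exp(logistic_normal_z(rng, n, 30))
        y = 1.0 * x + rng.normal(0, 1, n)  # direct effect, D independent of x
        return bray_dm(rel), x, y

    def test_null_calibration_with_direct_effect(self):
        rejections = 0
        n_rep = 500
        for seed in range(n_rep):
            dm, x, y = self._null_with_direct_effect(seed)
            res = md.distance_mediation_test(dm, x, y, n_perm=999, seed=seed)
            rejections += res.p_value <= 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_power_on_planted_chain(self):
        rejections = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(10_000 + seed)
            n = 60
            x = np.repeat([0.0, 1.0], n // 2)
            logits = rng.normal(0, 1, (n, 30))
            logits[:, :5] += x[:, None]  # x shifts taxa
            rel = np.exp(logits)
            rel /= rel.sum(1, keepdims=True)
            z = np.log(rel)
            y = (z[:, :5].mean(1) - z[:, 5:10].mean(1)) + rng.normal(0, 1, n)
            res = md.distance_mediation_test(bray_dm(rel), x, y, n_perm=199,
                                             seed=seed)
            rejections += res.p_value <= 0.05
        assert rejections / n_rep > 0.5

    def test_covariate_residualization(self, rng):
        dm, x, y = self._null_with_direct_effect(3)
        cov = pd.DataFrame({"batch": np.tile(["B1", "B2"], 24)})
        res = md.distance_mediation_test(dm, x, y, covariates=cov, n_perm=199,
                                         seed=0)
        assert 0 < res.p_value <= 1
        assert res.confounders == ("batch",)

    def test_sample_reordering_invariance(self):
        dm, x, y = self._null_with_direct_effect(5)
        res1 = md.distance_mediation_test(dm, x, y, n_perm=199, seed=7)
        perm = np.random.default_rng(1).permutation(len(x))
        dm2 = dv.DistanceMatrix([dm.ids[i] for i in perm],
                                dm.data[np.ix_(perm, perm)], dm.metric)
        res2 = md.distance_mediation_test(dm2, x[perm], y[perm], n_perm=199,
                                          seed=7)
        assert res1.indirect == pytest.approx(res2.indirect, abs=1e-10)

    def test_constant_input_rejected(self):
        dm, x, y = self._null_with_direct_effect(6)
        with pytest.raises(ValueError):
            md.distance_mediation_test(dm, np.zeros_like(x), y)


class TestNodeSubcomposition:
    def test_family_arithmetic(self, rng):
        import io
        from micromed.synthdata import read_taxonomy
        tree = read_taxonomy(io.StringIO(
            "((g__a:1,g__b:1)f__F1:1,(g__c:1)f__F2:1)root;"))
        table = pd.DataFrame({"g__a": [3, 30], "g__b": [7, 70],
                              "g__c": [5, 5]}, index=["s1", "s2"])
        sub = md.node_subcomposition(table, tree, "f__F1")
        np.testing.assert_allclose(sub.loc["s1"], [0.3, 0.7], atol=1e-12)

    def test_rare_child_pruned(self, rng):
        import io
        from micromed.synthdata import read_taxonomy
        tree = read_taxonomy(io.StringIO(
            "(g__a:1,g__b:1,g__c:1)f__F1;"))
        n = 30
        data = {"g__a": rng.integers(1, 9, n), "g__b": rng.integers(1, 9, n),
                "g__c": np.zeros(n)}
        data["g__c"][:2] = 5  # 2/30 = 6.7% detection -> pruned
        table = pd.DataFrame(data)
        sub = md.node_subcomposition(table, tree, "f__F1")
        assert list(sub.columns) == ["g__a", "g__b"]

    def test_single_surviving_child_skipped(self, rng):
        import io
        from micromed.synthdata import read_taxonomy
        tree = read_taxonomy(io.StringIO("(g__a:1,g__b:1)f__F1;"))
        table = pd.DataFrame({"g__a": np.ones(20), "g__b": np.zeros(20)})
        with pytest.raises(ValueError):
            md.node_subcomposition(table, tree, "f__F1")


class TestAlrTransform:
    def test_hand_example(self):
        sub = pd.DataFrame([[0.5, 0.3, 0.2]], columns=list("abc"))
        out = md.alr_transform(sub, reference="a")
        np.testing.assert_allclose(out.to_numpy()[0],
                                   [np.log(0.3 / 0.5), np.log(0.2 / 0.5)],
                                   atol=1e-12)
        np.testing.assert_allclose(out.to_numpy()[0], [-0.5108, -0.9163],
                                   atol=1e-4)

    def test_reference_defaults_to_most_abundant(self):
        sub = pd.DataFrame([[0.2, 0.5, 0.3], [0.1, 0.6, 0.3]],
                           columns=list("abc"))
        out = md.alr_transform(sub)
        assert all("/b)" in c for c in out.columns)

    def test_two_part_single_column(self):
        sub = pd.DataFrame([[0.4, 0.6]], columns=list("ab"))
        out = md.alr_transform(sub)
        assert out.shape[1] == 1

    def test_row_scaling_invariance(self, rng):
        sub = pd.DataFrame(rng.dirichlet(np.ones(4), 10), columns=list("abcd"))
        a = md.alr_transform(sub, reference="a")
        b = md.alr_transform(sub * 3.7, reference="a")
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)

    def test_zero_entries_rejected(self):
        with pytest.raises(ValueError):
            md.alr_transform(pd.DataFrame([[0.0, 1.0]], columns=list("ab")))


class TestMediateMultivariate:
    def test_noiseless_chain_full_mediation(self):
        n = 40
        x = np.repeat([0.0, 1.0], n // 2)
        # exact chain x -> M -> y (tiny jitter for identifiability of M vs x)
        m = x + np.random.default_rng(0).normal(0, 1e-6, n)
        y = m.copy()
        res = md.mediate_multivariate(x, m, y, B=199, seed=0)
        assert res.indirect == pytest.approx(res.total, abs=1e-4)
        assert res.direct == pytest.approx(0.0, abs=1e-4)

    def test_decomposition_identity(self, rng):
        n = 50
        x = np.repeat([0.0, 1.0], 25)
        m = rng.normal(size=(n, 3)) + x[:, None]
        y = m @ [0.5, -0.2, 0.1] + 0.3 * x + rng.normal(size=n)
        cov = pd.DataFrame({"batch": np.tile(["a", "b"], 25)})
        res = md.mediate_multivariate(x, m, y, covariates=cov, B=199, seed=1)
        assert res.total == pytest.approx(res.direct + res.indirect, abs=1e-10)
        assert sum(res.components.values()) == pytest.approx(res.indirect,
                                                             abs=1e-10)

    def test_null_mediator_calibrated(self):
        non_rejections = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            n = 48
            x = np.repeat([0.0, 1.0], n // 2)
            m = rng.normal(size=(n, 2))  # independent of x
            y = 0.8 * x + rng.normal(size=n)
            res = md.mediate_multivariate(x, m, y, B=199, seed=seed)
            non_rejections += res.p_value > 0.05
        assert non_rejections / n_rep >= 0.93

    def test_single_mediator_component_equals_joint(self, rng):
        n = 40
        x = np.repeat([0.0, 1.0], 20)
        m = x + rng.normal(0, 0.5, n)
        y = 2 * m + rng.normal(0, 0.5, n)
        res = md.mediate_multivariate(x, m, y, B=199, seed=2)
        assert list(res.components.values())[0] == pytest.approx(res.indirect,
                                                                 abs=1e-12)

    def test_too_many_mediators_rejected(self, rng):
        n = 20
        x = np.repeat([0.0, 1.0], 10)
        with pytest.raises(ValueError):
            md.mediate_multivariate(x, rng.normal(size=(n, 12)),
                                    rng.normal(size=n), B=199)


class TestTreeMediationScan:
    def test_planted_family_attains_minimum_p(self, design, taxonomy):
        hits = 0
        n_rep = 10
        fam = sorted(n.name for n in taxonomy.preorder()
                     if n.name and n.name.startswith("f__")
                     and len(list(n.tips())) >= 2)[0]
        leaves = [t.name for t in taxonomy.find(fam).tips()]
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            counts, meta, truth = sd.sample_counts(
                design, taxonomy, seed=seed, mediating_family=fam,
                community_shift_sd=0.25)
            x = (meta["community"] == "SubB").to_numpy(float)
            rel = zero_replace(counts)
            lr = np.log(rel[leaves[0]] / rel[leaves[1]]).to_numpy()
            y = 1.0 * (lr - lr.mean()) / lr.std() + rng.normal(0, 1.0, len(meta))
            scan = md.tree_mediation_scan(counts, taxonomy, x, y,
                                          covariates=meta[["batch"]],
                                          B=499, seed=seed)
            p_min = scan["P"].min()
            p_fam = scan.loc[scan["mediator"] == fam, "P"].iloc[0]
            hits += p_fam <= p_min + 1e-12
        assert hits / n_rep >= 0.8

    def test_single_eligible_node(self, rng):
        import io
        from micromed.synthdata import read_taxonomy
        tree = read_taxonomy(io.StringIO(
            "((g__a:1,g__b:1)f__F1:1)p__P1;"))
        n = 40
        table = pd.DataFrame({"g__a": rng.integers(1, 50, n),
                              "g__b": rng.integers(1, 50, n)})
        x = np.repeat([0.0, 1.0], n // 2)
        y = rng.normal(size=n)
        scan = md.tree_mediation_scan(table, tree, x, y, B=199, seed=0)
        # p__P1 has one child (skipped); f__F1 has two -> exactly one result
        assert len(scan) == 1
        assert scan["mediator"].iloc[0] == "f__F1"

    def test_child_order_invariance(self, rng):
        import io
        from micromed.synthdata import read_taxonomy
        t1 = read_taxonomy(io.StringIO("(g__a:1,g__b:1,g__c:1)f__F1;"))
        t2 = read_taxonomy(io.StringIO("(g__c:1,g__b:1,g__a:1)f__F1;"))
        n = 40
        table = pd.DataFrame({c: rng.integers(1, 50, n)
                              for c in ["g__a", "g__b", "g__c"]})
        x = np.repeat([0.0, 1.0], n // 2)
        y = table["g__a"].to_numpy() / 50 + rng.normal(0, 0.2, n)
        s1 = md.tree_mediation_scan(table, t1, x, y, B=199, seed=4)
        s2 = md.tree_mediation_scan(table, t2, x, y, B=199, seed=4)
        # ALR reference is the most abundant child either way: identical fit
        assert s1["indirect"].iloc[0] == pytest.approx(s2["indirect"].iloc[0],
                                                       abs=1e-10)


class TestModuleMediation:
    def test_planted_module_chain_power(self, rng):
        rejections = 0
        n_rep = 40
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            n = 60
            x = np.repeat([0.0, 1.0], 30)
            latent = x + r.normal(0, 0.7, n)
            eigs = pd.DataFrame({"turquoise": (latent - latent.mean())
                                 / latent.std()})
            y = latent + r.normal(0, 1.0, n)
            res = md.module_mediation(eigs, x, y, B=299, seed=seed)
            rejections += res.p_value < 0.05
        assert rejections / n_rep > 0.5

    def test_null_modules_calibrated(self):
        non_rej = 0
        n_rep = 100
        for seed in range(n_rep):
            r = np.random.default_rng(50_000 + seed)
            n = 48
            x = np.repeat([0.0, 1.0], 24)
            eigs = pd.DataFrame(r.normal(size=(n, 3)),
                                columns=["turquoise", "blue", "brown"])
            y = 0.5 * x + r.normal(size=n)
            res = md.module_mediation(eigs, x, y, B=199, seed=seed)
            non_rej += res.p_value > 0.05
        assert non_rej / n_rep >= 0.90

    def test_unclustered_features_standardized_and_included(self, rng):
        n = 40
        x = np.repeat([0.0, 1.0], 20)
        eigs = pd.DataFrame({"turquoise": rng.normal(size=n)})
        grey = pd.DataFrame({"feat_1": 5 + 3 * rng.normal(size=n)})
        y = rng.normal(size=n)
        res = md.module_mediation(eigs, x, y, unclustered=grey, B=199, seed=0)
        assert set(res.components) == {"turquoise", "feat_1"}
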