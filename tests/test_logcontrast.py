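import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from micromed import logcontrast as lc
from tests.conftest import logistic_normal_z


def slsqp_oracle(Z, y, lam):
    """Independent solver: split-variable QP via SLSQP (beta = u - v, u,v >= 0)."""
    n, p = Z.shape
    zc = Z - Z.mean(axis=0)
    yc = y - y.mean()

    def f(uv):
        b = uv[:p] - uv[p:]
        r = yc - zc @ b
        return (r @ r) / (2 * n) + lam * uv.sum()

    def grad(uv):
        b = uv[:p] - uv[p:]
        g = -(zc.T @ (yc - zc @ b)) / n
        return np.concatenate([g, -g]) + lam

    cons = [{"type": "eq",
             "fun": lambda uv: uv[:p].sum() - uv[p:].sum(),
             "jac": lambda uv: np.concatenate([np.ones(p), -np.ones(p)])}]
    res = minimize(f, np.zeros(2 * p), jac=grad, bounds=[(0, None)] * (2 * p),
                   constraints=cons, method="SLSQP",
                   options={"maxiter": 2000, "ftol": 1e-14})
    b = res.x[:p] - res.x[p:]
    return f(np.concatenate([np.maximum(b, 0), np.maximum(-b, 0)])), b


def objective(Z, y, beta, lam):
    n = len(y)
    zc = Z - Z.mean(axis=0)
    yc = y - y.mean()
    r = yc - zc @ beta
    return (r @ r) / (2 * n) + lam * np.abs(beta).sum()


def random_problem(seed, n=30, p=5, snr=3.0, support=None):
    rng = np.random.default_rng(seed)
    Z = logistic_normal_z(rng, n, p)
    beta = np.zeros(p)
    if support is None:
        beta[:2] = [1.0, -1.0]
    else:
        beta[:len(support)] = support
    sig = Z @ beta
    y = sig + rng.normal(0, max(sig.std(), 1.0) / np.sqrt(snr), n)
    return lc.LogContrastProblem(Z, y, [f"t{j}" for j in range(p)]), beta


class TestFitLogcontrast:
    def test_large_lambda_all_zero(self):
        prob, _ = random_problem(0)
        lam = 2 * lc.lambda_max(prob)
        beta, _ = lc.fit_logcontrast(prob, lam)
        assert np.all(beta == 0.0)

    def test_two_taxon_closed_form(self, rng):
        # p = 2 with zero-sum: beta1 = -beta2 = OLS slope of y on (z1 - z2)/2
        Z = logistic_normal_z(rng, 40, 2)
        y = 1.5 * (Z[:, 0] - Z[:, 1]) + rng.normal(0, 0.1, 40)
        prob = lc.LogContrastProblem(Z, y, ["a", "b"])
        beta, _ = lc.fit_logcontrast(prob, 0.0)
        d = Z[:, 0] - Z[:, 1]
        dc = d - d.mean()
        slope = dc @ (y - y.mean()) / (dc @ dc)
        assert beta[0] == pytest.approx(slope, abs=1e-8)
        assert beta[1] == pytest.approx(-slope, abs=1e-8)

    @pytest.mark.parametrize("seed", range(25))
    def test_objective_matches_independent_oracle(self, seed):
        prob, _ = random_problem(seed)
        lam = 0.3 * lc.lambda_max(prob)
        beta, _ = lc.fit_logcontrast(prob, lam)
        obj = objective(prob.Z, prob.y, beta, lam)
        obj_oracle, _ = slsqp_oracle(prob.Z, prob.y, lam)
        assert obj - obj_oracle < 1e-6
        assert abs(beta.sum()) <= 1e-8

    def test_compositional_invariance(self, rng):
        prob, _ = random_problem(3, n=40, p=8)
        lam = 0.2 * lc.lambda_max(prob)
        beta, _ = lc.fit_logcontrast(prob, lam)
        scale = rng.uniform(0.1, 10.0, size=40)
        z2 = prob.Z + np.log(scale)[:, None]
        prob2 = object.__new__(lc.LogContrastProblem)
        prob2.Z, prob2.y, prob2.taxa = z2, prob.y, prob.taxa
        beta2, _ = lc.fit_logcontrast(prob2, lam)
        assert np.abs(beta - beta2).max() <= 1e-8

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            lc.LogContrastProblem(np.array([[np.inf, 0.0]]), np.array([1.0]),
                                  ["a", "b"])


class TestCvLambda:
    def test_pure_noise_chooses_near_lambda_max(self):
        near_max, empty_support = 0, 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            Z = logistic_normal_z(rng, 50, 10)
            y = rng.normal(size=50)
            prob = lc.LogContrastProblem(Z, y, [f"t{j}" for j in range(10)])
            lam, _ = lc.cv_lambda(prob, seed=seed)
            beta, _ = lc.fit_logcontrast(prob, lam)
            near_max += lam >= 0.1 * lc.lambda_max(prob)
            empty_support += (np.abs(beta) > lc.SELECT_TOL).sum() <= 3
        assert near_max >= 15
        assert empty_support >= 15

    def test_strong_signal_interior_minimum(self):
        prob, _ = random_problem(7, n=60, p=10, snr=3.0,
                                 support=[1.0, -1.0, 0.8, -0.8])
        lam, curve = lc.cv_lambda(prob, seed=0)
        mse = curve["cv_mse"].to_numpy()
        best = int(np.argmin(mse))
        assert 0 < best < len(mse) - 1

    def test_deterministic_for_fixed_seed(self):
        prob, _ = random_problem(2)
        lam1, c1 = lc.cv_lambda(prob, seed=5)
        lam2, c2 = lc.cv_lambda(prob, seed=5)
        assert lam1 == lam2
        pd.testing.assert_frame_equal(c1, c2)

    def test_too_many_folds_rejected(self):
        prob, _ = random_problem(1, n=5)
        with pytest.raises(ValueError):
            lc.cv_lambda(prob, n_folds=10)


class TestSelectionProbabilities:
    def test_single_bootstrap_gives_zero_one(self):
        prob, _ = random_problem(4, n=40, p=6)
        bcv = lc.bootstrap_selection(prob, B=1, seed=0)
        assert set(np.unique(bcv)) <= {0.0, 1.0}

    def test_planted_taxon_high_null_taxon_low(self):
        prob, beta = random_problem(9, n=100, p=10, snr=3.0,
                                    support=[1.2, -1.2])
        bcv = lc.bootstrap_selection(prob, B=30, seed=1)
        assert bcv[0] >= 0.9 and bcv[1] >= 0.9
        # CV-minimum tuning keeps null bootstrap frequencies well below the
        # planted taxa but not near zero (the familiar liberal bcv behaviour)
        assert bcv[5:].mean() < bcv[:2].mean() - 0.2

    def test_stability_deterministic(self):
        prob, _ = random_problem(5, n=40, p=6)
        a = lc.stability_selection(prob, B=10, seed=3)
        b = lc.stability_selection(prob, B=10, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_permuted_response_rarely_stable(self):
        # y carries no signal: no taxon should look stable
        exceed = 0
        for seed in range(10):
            rng = np.random.default_rng(seed + 100)
            Z = logistic_normal_z(rng, 60, 12)
            y = rng.normal(size=60)
            prob = lc.LogContrastProblem(Z, y, [f"t{j}" for j in range(12)])
            stab = lc.stability_selection(prob, B=30, seed=seed)
            exceed += stab.max() >= 0.85
        assert exceed <= 1

    def test_small_subsample_rejected(self):
        prob, _ = random_problem(6, n=10)
        with pytest.raises(ValueError):
            lc.stability_selection(prob, B=5, frac=0.2)


class TestRefitAndFilter:
    def test_stability_threshold_strict(self):
        prob, _ = random_problem(8, n=40, p=5)
        stab = np.array([0.84, 0.90, 0.0, 0.95, 0.2])
        res = lc.refit_and_filter(prob, stab)
        assert not res["in_support"].iloc[0]  # 0.84 < 0.85, never refit
        assert res["in_support"].iloc[1] and res["in_support"].iloc[3]
        assert res["refitted_coef"].iloc[0] == 0.0

    def test_low_coefficient_excluded_but_reported(self):
        prob, _ = random_problem(8, n=40, p=5)
        stab = np.array([0.9, 0.9, 0.9, 0.9, 0.9])
        res = lc.refit_and_filter(prob, stab, coef_cut=10.0)
        assert res["in_support"].all()
        assert not res["in_network"].any()
        assert len(res) == 5

    def test_single_supported_taxon_forced_zero(self):
        prob, _ = random_problem(8, n=40, p=5)
        stab = np.array([0.99, 0.0, 0.0, 0.0, 0.0])
        res = lc.refit_and_filter(prob, stab)
        assert res["refitted_coef"].iloc[0] == 0.0
        assert not res["in_network"].iloc[0]

    def test_refit_zero_sum(self):
        prob, _ = random_problem(10, n=50, p=8)
        stab = np.array([0.9, 0.9, 0.9, 0.0, 0.9, 0.0, 0.9, 0.0])
        res = lc.refit_and_filter(prob, stab)
        assert abs(res["refitted_coef"].sum()) <= 1e-8

    def test_empty_support_empty_result(self):
        prob, _ = random_problem(8, n=40, p=5)
        res = lc.refit_and_filter(prob, np.zeros(5))
        assert not res["in_support"].any()
        assert (res["refitted_coef"] == 0).all()


class TestBuildNetwork:
    def test_no_selection_empty_edges(self):
        prob, _ = random_problem(8, n=40, p=5)
        res = lc.refit_and_filter(prob, np.zeros(5))
        edges = lc.build_network({"m1": res})
        assert len(edges) == 0

    def test_edges_respect_coef_cut_and_sign(self):
        prob, beta = random_problem(11, n=80, p=8,
                                    support=[1.0, -1.0, 0.8, -0.8])
        stab = np.array([0.9, 0.9, 0.9, 0.9, 0.0, 0.0, 0.0, 0.0])
        res = lc.refit_and_filter(prob, stab)
        edges = lc.build_network({"resp": res},
                                 response_annotations={"resp": "lipid"})
        assert (edges["weight"] >= 0.1).all()
        for _, e in edges.iterrows():
            j = prob.taxa.index(e["taxon"])
            if beta[j] != 0:
                assert np.sign(beta[j]) == e["sign"]
        g = lc.network_to_graph(edges)
        assert g.number_of_edges() == len(edges)


def test_driver_taxa_recovered_in_network(design, study_data):
    """Taxa driving a planted omics block are recovered with correct signs."""
    from micromed import synthdata as sd
    from micromed.preprocess import zero_replace

    counts, meta, _ = study_data
    z = np.log(zero_replace(counts))
    w = np.zeros(counts.shape[1])
    w[3], w[9] = 1.0, -1.0
    om, _, truth = sd.make_omics(design, 60, 2, within_block_corr=0.8, seed=8,
                                 block_size=25, taxa_driver={0: w},
                                 taxa_logrel=z)
    # response: the driven block's latent factor proxy (block feature mean)
    block1 = [f for f, l in truth.module_labels_true.items() if l == 1]
    y = om[block1].mean(axis=1).to_numpy()
    prob = lc.LogContrastProblem(np.asarray(z), y, list(counts.columns))
    stab = lc.stability_selection(prob, B=50, seed=0)
    res = lc.refit_and_filter(prob, stab)
    assert res["in_network"].iloc[3] and res["in_network"].iloc[9]
    assert res["refitted_coef"].iloc[3] > 0 > res["refitted_coef"].iloc[9]
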