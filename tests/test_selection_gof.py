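from dataclasses import dataclass

import numpy as np
import pytest

import spinnerpop as sp
from spinnerpop.selection_gof import _chi2_2xc, global_c_hat


@dataclass
class FakeFit:
    loglik: float
    K: int
    n_individuals: int

    class _S:
        def __init__(self, name):
            self._name = name

        def label(self):
            return self._name

    def __post_init__(self):
        self.structure = self._S(f"ll={self.loglik},K={self.K}")


class TestInformationCriteria:
    def test_hand_computed_value(self):
        # -2(-100) + 2*5 + 2*5*6/(50-6) = 211.3636...
        assert sp.aicc(-100, 5, 50) == pytest.approx(200 + 10 + 60 / 44)

    def test_large_sample_limit_is_aic(self):
        assert sp.aicc(-100, 5, 10 ** 9) == pytest.approx(210, abs=1e-5)

    def test_qaicc_at_unit_c_hat(self):
        # c-hat = 1: only the extra variance-inflation parameter differs
        a = sp.aicc(-100, 6, 100)
        q = sp.qaicc(-100, 5, 100, 1.0)
        assert q == pytest.approx(a)

    def test_small_ess_rejected(self):
        with pytest.raises(ValueError):
            sp.aicc(-10, 5, 6)


class TestRanking:
    def test_reported_delta(self):
        # best and third-ranked criterion values from the study's table
        table = sp.rank_models([FakeFit(-3907.6 / 2, 0, 300),
                                FakeFit(-3964.7 / 2, 0, 300)])
        assert table["delta"].iloc[1] == pytest.approx(57.1)

    def test_single_model_weight_one(self):
        t = sp.rank_models([FakeFit(-50, 2, 100)])
        assert t["weight"].iloc[0] == 1.0

    def test_tied_models_split_weight(self):
        t = sp.rank_models([FakeFit(-50, 2, 100), FakeFit(-50, 2, 100)])
        np.testing.assert_allclose(t["weight"], [0.5, 0.5])

    def test_weights_sum_to_one_and_shift_invariant(self):
        fits = [FakeFit(-50, 2, 100), FakeFit(-53, 3, 100),
                FakeFit(-60, 4, 100)]
        t1 = sp.rank_models(fits)
        assert t1["weight"].sum() == pytest.approx(1.0)
        shifted = [FakeFit(f.loglik - 10, f.K, 100) for f in fits]
        t2 = sp.rank_models(shifted)
        np.testing.assert_allclose(t1["weight"], t2["weight"], atol=1e-12)

    def test_mismatched_data_rejected(self):
        with pytest.raises(ValueError, match="same data"):
            sp.rank_models([FakeFit(-50, 2, 100), FakeFit(-50, 2, 101)])


class TestModelAverage:
    def _fit_pair(self):
        design = sp.study_design(4, 3)
        truth = sp.study_truth(design)
        matrix, _ = sp.simulate_msord(truth, design, 120, seed=31)
        st_m = sp.ModelStructure(s="constant", p="constant", pent="constant",
                                 phi="constant", emigration="markovian",
                                 psi_time=False)
        st_r = sp.ModelStructure(s="constant", p="constant", pent="constant",
                                 phi="constant", emigration="random",
                                 psi_time=False)
        return (sp.fit_msord(matrix, st_m, n_restarts=1),
                sp.fit_msord(matrix, st_r, n_restarts=1))

    def test_average_between_component_estimates(self):
        f1, f2 = self._fit_pair()
        avg = sp.model_average([f1, f2])
        e1, e2 = f1.natural_estimates(), f2.natural_estimates()
        for row in avg.itertuples():
            lo = min(e1[row.parameter], e2[row.parameter]) - 1e-9
            hi = max(e1[row.parameter], e2[row.parameter]) + 1e-9
            assert lo <= row.estimate <= hi

    def test_unconditional_se_at_least_weighted_within(self):
        f1, f2 = self._fit_pair()
        avg = sp.model_average([f1, f2]).set_index("parameter")
        s1, s2 = f1.natural_ses(), f2.natural_ses()
        for name in s1:
            assert avg.loc[name, "se_unconditional"] >= \
                min(s1[name], s2[name]) - 1e-9


class TestCJS:
    def make_cjs_data(self, phi, p, n=400, T=6, seed=0):
        rng = np.random.default_rng(seed)
        det = np.zeros((n, T), dtype=np.int8)
        det[:, 0] = 1  # release everyone at occasion 1
        for i in range(n):
            alive = True
            for t in range(1, T):
                alive = alive and rng.random() < phi
                if alive and rng.random() < p:
                    det[i, t] = 1
        return det

    def test_perfect_detection_zero_deviance(self):
        det = self.make_cjs_data(1.0, 1.0, n=60, T=5)
        fit = sp.cjs_fit(det)
        assert fit.deviance == pytest.approx(0.0, abs=1e-3)

    def test_cjs_equals_m_array_multinomial(self):
        # the CJS likelihood is exactly the product of cohort multinomials,
        # so the saturated likelihood bounds it above
        det = self.make_cjs_data(0.8, 0.5, n=300, T=5, seed=4)
        fit = sp.cjs_fit(det)
        assert fit.loglik <= fit.loglik_saturated + 1e-9
        assert fit.deviance >= 0.0

    def test_recovery(self):
        det = self.make_cjs_data(0.85, 0.55, n=2000, T=6, seed=9)
        fit = sp.cjs_fit(det)
        # interior parameters (the last phi*p product is confounded)
        assert np.allclose(fit.phi[:-1], 0.85, atol=0.08)
        assert np.allclose(fit.p[:-1], 0.55, atol=0.08)

    def test_too_few_occasions(self):
        with pytest.raises(ValueError):
            sp.cjs_fit(np.array([[1, 1], [1, 0]]))


class TestCHat:
    def test_reported_global_arithmetic(self):
        assert global_c_hat([531], [384]) == pytest.approx(1.38, abs=0.005)
        assert global_c_hat([49], [23]) == pytest.approx(2.13, abs=0.005)

    def test_ratio_of_sums_not_mean_of_ratios(self):
        chi2 = [10.0, 90.0]
        df = [10, 30]
        assert global_c_hat(chi2, df) == pytest.approx(100 / 40)
        assert global_c_hat(chi2, df) != pytest.approx(
            np.mean([1.0, 3.0]))

    def test_per_primary_table(self):
        design = sp.study_design()
        matrix, _ = sp.simulate_msord(sp.study_truth(design), design, 200,
                                      seed=17)
        tab = sp.median_c_hat(matrix)
        assert tab["period"].iloc[-1] == "global"
        body = tab.iloc[:-1]
        assert (body["df"] > 0).all()
        np.testing.assert_allclose(body["c_hat"],
                                   body["deviance"] / body["df"])
        glob = tab.iloc[-1]
        assert glob["c_hat"] == pytest.approx(
            body["deviance"].sum() / body["df"].sum())

    def test_zero_deviance_zero_c_hat(self):
        assert global_c_hat([0.0], [10]) == 0.0


class TestReleaseTests:
    def test_symmetric_table_zero_chi2(self):
        assert _chi2_2xc(np.array([[10, 10], [10, 10]])) == (0.0, 1)

    def test_null_calibration(self):
        # homogeneous CJS data: chi2/df should hover near 1 over replicates
        ratios = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            n, T = 250, 8
            det = np.zeros((n, T), dtype=np.int8)
            entry = rng.integers(0, T - 2, n)
            for i in range(n):
                alive = True
                for t in range(entry[i], T):
                    if t > entry[i]:
                        alive = alive and rng.random() < 0.9
                    if alive and rng.random() < 0.5:
                        det[i, t] = 1
            det = det[det.sum(axis=1) > 0]
            design = sp.StudyDesign.balanced(T, 1)
            pooled = sp.PooledMatrix([f"i{k}" for k in range(len(det))],
                                     det, design)
            res = sp.release_tests(pooled)
            for key in ("test2", "test3"):
                if res[key]["df"] > 0:
                    ratios.append(res[key]["chi2"] / res[key]["df"])
        mean_ratio = float(np.mean(ratios))
        # chi2/df has mean 1 under the null; MC error with ~80 components
        assert 0.8 < mean_ratio < 1.25, mean_ratio

    def test_detection_heterogeneity_inflates_test2(self):
        rng = np.random.default_rng(123)
        n, T = 600, 8
        det = np.zeros((n, T), dtype=np.int8)
        p_class = np.where(rng.random(n) < 0.5, 0.85, 0.15)  # two classes
        for i in range(n):
            for t in range(T):
                if rng.random() < p_class[i]:
                    det[i, t] = 1
        det = det[det.sum(axis=1) > 0]
        design = sp.StudyDesign.balanced(T, 1)
        pooled = sp.PooledMatrix([f"i{k}" for k in range(len(det))], det,
                                 design)
        res = sp.release_tests(pooled)
        assert res["test2"]["chi2"] / res["test2"]["df"] > 2.0

    def test_too_few_occasions(self):
        design = sp.StudyDesign.balanced(2, 1)
        pooled = sp.PooledMatrix(["a"], np.array([[1, 1]]), design)
        with pytest.raises(ValueError):
            sp.release_tests(pooled)


class TestDataCloning:
    def test_se_ratio_scales_as_inverse_sqrt_K(self):
        design = sp.study_design(5, 4)
        truth = sp.study_truth(design)
        matrix, _ = sp.simulate_msord(truth, design, 150, seed=23)
        st = sp.ModelStructure(s="constant", p="constant", pent="constant",
                               phi="constant", emigration="markovian",
                               psi_time=False)
        table = sp.data_cloning(matrix, st, K_clones=25, seed=23)
        interior = table[table["verdict"] != "flagged"]
        assert len(interior) > 0
        # estimable parameters: SE shrinks like 1/sqrt(K), estimates fixed
        assert (interior["verdict"] == "estimable").all(), \
            interior[["parameter", "se_ratio", "verdict"]]
        np.testing.assert_allclose(interior["estimate"],
                                   interior["estimate_cloned"], atol=5e-3)
        np.testing.assert_allclose(interior["se_ratio"], 1 / np.sqrt(25),
                                   rtol=0.25)

    def test_reference_lines_reported(self):
        design = sp.study_design(4, 3)
        truth = sp.study_truth(design)
        matrix, _ = sp.simulate_msord(truth, design, 80, seed=29)
        st = sp.ModelStructure(s="constant", p="constant", pent="constant",
                               phi="constant", emigration="markovian",
                               psi_time=False)
        table = sp.data_cloning(matrix, st, K_clones=16, seed=29)
        assert (table["expected_sqrt"] == 0.25).all()
        assert (table["expected_linear"] == 1 / 16).all()

    def test_invalid_K(self):
        with pytest.raises(ValueError):
            sp.data_cloning(None, None, K_clones=1)
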