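import itertools
import math

import numpy as np
import pytest

import spinnerpop as sp
from spinnerpop.msord import window_masses

from conftest import random_msord_params


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive re-implementations)
# ---------------------------------------------------------------------------

def oracle_window_mass(pent, phi, a, d):
    J = len(pent)
    mass = pent[a]
    for j in range(a, d):
        mass *= phi[j]
    if d < J - 1:
        mass *= 1.0 - phi[d]
    return mass


def oracle_within_primary(omega, pent, phi, p):
    """Sum over availability windows, scalar arithmetic only."""
    J = len(pent)
    total = 0.0
    for a in range(J):
        for d in range(a, J):
            if any(omega[j] for j in range(0, a)) or \
                    any(omega[j] for j in range(d + 1, J)):
                continue
            emit = 1.0
            for j in range(a, d + 1):
                emit *= p[j] if omega[j] else 1.0 - p[j]
            total += oracle_window_mass(pent, phi, a, d) * emit
    return total


def oracle_history_prob(hist, params, design):
    """Exhaustive enumeration over latent state sequences."""
    T = design.n_primary
    blocks = [np.asarray(hist)[design.primary_slice(t)] for t in range(T)]
    first = next(t for t in range(T) if blocks[t].sum() > 0)

    def emit(t, state):
        if state == 0:  # present
            return oracle_within_primary(blocks[t], params.pent[t],
                                         params.phi[t], params.p[t])
        return 1.0 if blocks[t].sum() == 0 else 0.0

    ps = 1.0 - oracle_within_primary(np.zeros_like(blocks[first]),
                                     params.pent[first], params.phi[first],
                                     params.p[first])
    total = 0.0
    for seq in itertools.product([0, 1, 2], repeat=T - first - 1):
        pr = emit(first, 0) / ps
        prev = 0
        for k, state in enumerate(seq):
            t = first + 1 + k
            S = params.S[t - 1]
            pe, ee = params.psi_PE[t - 1], params.psi_EE[t - 1]
            if prev == 2:
                pr *= 1.0 if state == 2 else 0.0
            elif state == 2:
                pr *= 1.0 - S
            elif state == 0:
                pr *= S * ((1 - pe) if prev == 0 else (1 - ee))
            else:
                pr *= S * (pe if prev == 0 else ee)
            if pr == 0.0:
                break
            pr *= emit(t, state)
            if pr == 0.0:
                break
            prev = state
        else:
            total += pr
    return total


# ---------------------------------------------------------------------------
# within-primary sub-model
# ---------------------------------------------------------------------------

class TestWithinPrimary:
    def test_single_occasion_is_p(self):
        assert sp.within_primary_prob([1], [1.0], [], [0.37]) == \
            pytest.approx(0.37)

    def test_always_available_all_zero(self):
        val = sp.within_primary_prob([0, 0], [1.0, 0.0], [1.0], [0.4, 0.6])
        assert val == pytest.approx(0.6 * 0.4)

    @pytest.mark.parametrize("J", [1, 2, 3, 4])
    def test_emissions_sum_to_one(self, rng, J):
        for _ in range(5):
            pent = rng.dirichlet(np.ones(J))
            phi = rng.random(max(J - 1, 0))
            p = rng.random(J)
            total = sum(
                sp.within_primary_prob(list(om), pent, phi, p)
                for om in itertools.product([0, 1], repeat=J))
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_matches_naive_window_sum(self, rng):
        J = 4
        pent = rng.dirichlet(np.ones(J))
        phi = rng.random(J - 1)
        p = rng.random(J)
        for om in itertools.product([0, 1], repeat=J):
            assert sp.within_primary_prob(list(om), pent, phi, p) == \
                pytest.approx(oracle_within_primary(om, pent, phi, p),
                              abs=1e-13)

    def test_bad_pent_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            sp.within_primary_prob([1, 0], [0.5, 0.4], [0.5], [0.5, 0.5])


class TestPstar:
    def test_no_detection_possible(self):
        assert sp.pstar([1.0, 0.0], [0.8], [0.0, 0.0]) == 0.0

    def test_closed_form_always_present(self):
        J, p = 5, 0.3
        pent = [1.0] + [0.0] * (J - 1)
        phi = [1.0] * (J - 1)
        assert sp.pstar(pent, phi, [p] * J) == pytest.approx(
            1 - (1 - p) ** J)

    def test_complements_all_zero_history(self, rng):
        J = 4
        pent = rng.dirichlet(np.ones(J))
        phi = rng.random(J - 1)
        p = rng.random(J)
        assert sp.pstar(pent, phi, p) == pytest.approx(
            1.0 - sp.within_primary_prob([0] * J, pent, phi, p))


# ---------------------------------------------------------------------------
# full history likelihood
# ---------------------------------------------------------------------------

class TestHistoryLoglik:
    def test_hand_expansion_then_missing(self):
        d = sp.StudyDesign.balanced(2, 1)
        params = sp.MSORDParams(
            S=np.array([0.9]), p=[np.array([0.3])] * 2,
            pent=[np.array([1.0])] * 2, phi=[np.zeros(0)] * 2,
            psi_PE=np.array([0.4]), psi_EE=np.array([0.6]))
        expected = math.log(0.9 * (0.4 + 0.6 * 0.7) + 0.1)
        assert sp.history_loglik([1, 0], params, d) == pytest.approx(expected)

    def test_hand_expansion_reseen(self):
        d = sp.StudyDesign.balanced(2, 1)
        params = sp.MSORDParams(
            S=np.array([0.9]), p=[np.array([0.3])] * 2,
            pent=[np.array([1.0])] * 2, phi=[np.zeros(0)] * 2,
            psi_PE=np.array([0.4]), psi_EE=np.array([0.6]))
        assert sp.history_loglik([1, 1], params, d) == pytest.approx(
            math.log(0.9 * 0.6 * 0.3))

    def test_matches_latent_enumeration_oracle(self, rng):
        design = sp.StudyDesign.balanced(3, 2)
        for rep in range(3):
            params = random_msord_params(rng, design)
            for hist in itertools.product([0, 1], repeat=6):
                if sum(hist) == 0:
                    continue
                ll = sp.history_loglik(list(hist), params, design)
                oracle = oracle_history_prob(list(hist), params, design)
                assert math.exp(ll) == pytest.approx(oracle, abs=1e-10)

    def test_all_zero_history_rejected(self, rng, small_design):
        params = random_msord_params(rng, small_design)
        with pytest.raises(ValueError):
            sp.history_loglik([0] * 6, params, small_design)


class TestTotalLoglik:
    def test_additivity_and_permutation(self, rng, small_design):
        params = random_msord_params(rng, small_design)
        det = np.array([[1, 0, 0, 1, 0, 0],
                        [0, 1, 1, 0, 0, 1],
                        [0, 0, 0, 0, 1, 0]], dtype=np.int8)
        m = sp.CaptureMatrix(["a", "b", "c"], det, small_design)
        total = sp.msord_loglik(m, params)
        parts = sum(sp.history_loglik(list(row), params, small_design)
                    for row in det)
        assert total == pytest.approx(parts)
        perm = sp.CaptureMatrix(["c", "a", "b"], det[[2, 0, 1]], small_design)
        assert sp.msord_loglik(perm, params) == pytest.approx(total)

    def test_duplicated_individual_doubles(self, rng, small_design):
        params = random_msord_params(rng, small_design)
        det = np.array([[1, 0, 1, 0, 0, 0]], dtype=np.int8)
        one = sp.CaptureMatrix(["a"], det, small_design)
        two = sp.CaptureMatrix(["a", "b"], np.vstack([det, det]),
                               small_design)
        assert sp.msord_loglik(two, params) == pytest.approx(
            2 * sp.msord_loglik(one, params))


# ---------------------------------------------------------------------------
# model structures and fitting
# ---------------------------------------------------------------------------

class TestModelStructure:
    def test_parse_study_notation(self):
        st = sp.ModelStructure.from_string(
            "S(.) p(.) pent(season.day) phi(season.day) psi(Markovian)")
        assert st.s == "constant" and st.p == "constant"
        assert st.pent == "season.day" and st.phi == "season.day"
        assert st.emigration == "markovian" and st.psi_time

    def test_parse_variants(self):
        st = sp.ModelStructure.from_string(
            "S(.) p(season) pent(.) phi(t) psi(random,constant)")
        assert st.p == "season" and st.phi == "season.day"
        assert st.emigration == "random" and not st.psi_time
        assert sp.ModelStructure.from_string(
            "S(.) p(.) pent(.) phi(.) psi(none)").emigration == "none"

    def test_parameter_counts(self):
        from spinnerpop.msord import ParamLayout
        design = sp.study_design()
        st = sp.ModelStructure(s="constant", p="constant", pent="constant",
                               phi="constant", emigration="markovian",
                               psi_time=False)
        # S + p + 5 shared pent cells + phi + 2 psi
        assert ParamLayout(st, design).n_free == 10
        full = sp.ModelStructure.from_string(
            "S(.) p(.) pent(season.day) phi(season.day) psi(Markovian)")
        assert ParamLayout(full, design).n_free == 1 + 1 + 40 + 40 + 14


class TestFitting:
    def test_parameter_recovery_single_large_dataset(self, study_scale,
                                                     simple_structure):
        design, truth = study_scale
        matrix, _ = sp.simulate_msord(truth, design, 500, seed=77)
        fit = sp.fit_msord(matrix, simple_structure, n_restarts=1)
        assert fit.converged
        est, ses = fit.natural_estimates(), fit.natural_ses()
        for name, true_val in [("S[1->2]", 0.95), ("p[1,1]", 0.3),
                               ("psi_PE[1->2]", 0.35),
                               ("psi_EE[1->2]", 0.55), ("phi[1,1]", 0.8)]:
            assert abs(est[name] - true_val) < 3 * ses[name], name

    def test_random_equals_tied_markovian_loglik(self, study_scale):
        design, truth = study_scale
        matrix, _ = sp.simulate_msord(truth, design, 120, seed=3)
        random_st = sp.ModelStructure(s="constant", p="constant",
                                      pent="constant", phi="constant",
                                      emigration="random", psi_time=False)
        fit = sp.fit_msord(matrix, random_st, n_restarts=1,
                           compute_cov=False)
        # evaluating the Markovian likelihood at the tied estimates
        # reproduces the random-emigration maximum
        assert sp.msord_loglik(matrix, fit.params) == pytest.approx(
            fit.loglik, abs=1e-8)
        np.testing.assert_allclose(fit.params.psi_PE, fit.params.psi_EE)

    def test_markovian_nests_random(self, study_scale, simple_structure):
        design, truth = study_scale
        matrix, _ = sp.simulate_msord(truth, design, 120, seed=3)
        random_st = sp.ModelStructure(s="constant", p="constant",
                                      pent="constant", phi="constant",
                                      emigration="random", psi_time=False)
        ll_random = sp.fit_msord(matrix, random_st, n_restarts=2,
                                 compute_cov=False).loglik
        ll_markov = sp.fit_msord(matrix, simple_structure, n_restarts=2,
                                 compute_cov=False).loglik
        assert ll_markov >= ll_random - 1e-6

    def test_determinism(self, study_scale, simple_structure):
        design, truth = study_scale
        matrix, _ = sp.simulate_msord(truth, design, 60, seed=9)
        f1 = sp.fit_msord(matrix, simple_structure, seed=4, n_restarts=2,
                          compute_cov=False)
        f2 = sp.fit_msord(matrix, simple_structure, seed=4, n_restarts=2,
                          compute_cov=False)
        np.testing.assert_array_equal(f1.x, f2.x)


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def fitted():
    design = sp.study_design()
    truth = sp.study_truth(design)
    matrix, truth_sim = sp.simulate_msord(truth, design, 300, seed=15)
    st = sp.ModelStructure(s="constant", p="constant", pent="constant",
                           phi="constant", emigration="markovian",
                           psi_time=False)
    return sp.fit_msord(matrix, st, n_restarts=1), matrix, truth_sim


class TestDerived:
    def test_abundance_tracks_truth(self, fitted):
        fit, matrix, truth_sim = fitted
        table = sp.derive_abundance(fit, matrix)
        available = (truth_sim.alive & (truth_sim.state == 1)).sum(axis=0)
        for t, row in table.iterrows():
            assert abs(row["N_m"] - available[t]) < 4 * row["se_total"], \
                (t, row["N_m"], available[t])

    def test_abundance_monotone_in_pstar(self):
        # N_m = n / p*: larger detectability, smaller estimate
        assert 50 / 0.9 < 50 / 0.5

    def test_perfect_detection_gives_count(self, study_scale):
        design, _ = study_scale
        truth = sp.study_truth(design, p=1.0, phi=1.0,
                               pent=np.eye(6)[0], psi_PE=0.2, psi_EE=0.4)
        matrix, _ = sp.simulate_msord(truth, design, 50, seed=2)
        st = sp.ModelStructure(s="constant", p="constant", pent="constant",
                               phi="constant", emigration="markovian",
                               psi_time=False)
        fit = sp.fit_msord(matrix, st, n_restarts=1)
        table = sp.derive_abundance(fit, matrix)
        counts = [(matrix.primary_block(t).sum(axis=1) > 0).sum()
                  for t in range(design.n_primary)]
        # p* -> 1, so the estimate collapses to the observed count
        np.testing.assert_allclose(table["N_m"], counts, rtol=1e-3)

    def test_transition_complements(self, fitted):
        fit, _, _ = fitted
        tab = sp.derived_transitions(fit)
        np.testing.assert_allclose(tab["psi_PE"] + tab["psi_PP"], 1.0)
        np.testing.assert_allclose(tab["psi_EE"] + tab["psi_EP"], 1.0)
        np.testing.assert_allclose(tab["se_psi_PP"], tab["se_psi_PE"])
        # reported pattern: a 0.67 emigration probability leaves 0.33
        assert 1.0 - 0.67 == pytest.approx(0.33)

    def test_residence_time_bounds_and_oracle(self, fitted, rng):
        fit, _, _ = fitted
        res = sp.residence_time(fit)
        assert ((res >= 1.0) & (res <= 6.0)).all()
        # enumeration oracle at J=4 with explicit scalar loops
        pent = rng.dirichlet(np.ones(4))
        phi = rng.random(3)
        expect = 0.0
        for a in range(4):
            for d in range(a, 4):
                expect += oracle_window_mass(pent, phi, a, d) * (d - a + 1)
        M = window_masses(pent, phi)
        lengths = np.abs(np.subtract.outer(np.arange(4), np.arange(4))) + 1
        assert float((M * lengths).sum()) == pytest.approx(expect)

    def test_residence_degenerate_cases(self):
        M = window_masses(np.array([1.0, 0, 0, 0]), np.ones(3))
        lengths = np.abs(np.subtract.outer(np.arange(4), np.arange(4))) + 1
        assert float((M * lengths).sum()) == pytest.approx(4.0)
        M0 = window_masses(np.array([0.25] * 4), np.zeros(3))
        assert float((M0 * lengths).sum()) == pytest.approx(1.0)
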