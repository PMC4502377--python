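import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from palmpop import (
    AdmixtureModel,
    align_runs,
    assign_populations,
    evanno_delta_k,
    fit_admixture,
)
from palmpop.admixture import similarity
from palmpop.matrix import MISSING

from conftest import make_matrix


def _ingroup(two_pop_sim):
    gm, sheet, *_ = two_pop_sim
    keep = [
        s
        for s, sp, dup in zip(
            sheet.table["sample"], sheet.table["species"], sheet.table["duplicate_of"]
        )
        if sp == "P_dactylifera" and not dup
    ]
    return gm.take_samples(keep), sheet.table.set_index("sample").loc[keep, "region"]


class TestGibbs:
    def test_single_population_degenerates_to_frequency_estimate(self, rng):
        dosage = rng.integers(0, 3, size=(12, 60))
        run = fit_admixture(make_matrix(dosage), K=1, burn_in=100, n_reps=400, seed=3)
        assert np.all(run.Q == 1.0)
        emp = dosage.mean(axis=0) / 2.0
        assert np.abs(run.P[0] - emp).max() < 0.1

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            fit_admixture(make_matrix(np.zeros((3, 5))), K=4, burn_in=1, n_reps=1)

    def test_q_rows_sum_to_one_and_trace_finite(self, two_pop_sim):
        gm, _ = _ingroup(two_pop_sim)
        run = fit_admixture(gm, K=2, burn_in=100, n_reps=300, seed=9)
        np.testing.assert_allclose(run.Q.sum(axis=1), 1.0, atol=1e-9)
        assert np.isfinite(run.loglik_trace).all()
        assert len(run.loglik_trace) == 400
        assert ((run.P >= 0) & (run.P <= 1)).all()

    def test_two_pop_likelihood_beats_one_pop(self, two_pop_sim):
        gm, _ = _ingroup(two_pop_sim)
        l1 = fit_admixture(gm, K=1, burn_in=100, n_reps=400, seed=5).mean_loglik
        l2 = fit_admixture(gm, K=2, burn_in=100, n_reps=400, seed=5).mean_loglik
        assert l2 > l1

    def test_recovery_of_diverged_populations(self, two_pop_sim):
        gm, regions = _ingroup(two_pop_sim)
        run = fit_admixture(gm, K=2, burn_in=300, n_reps=1200, seed=17)
        unadmixed = (regions != "Central").to_numpy()
        frac = (run.Q.max(axis=1) >= 0.9)[unadmixed].mean()
        assert frac >= 0.95
        # the two source populations land in different components
        west = (regions == "North_Africa").to_numpy()
        east = (regions == "Arabian_Gulf").to_numpy()
        west_comp = run.Q[west].mean(axis=0).argmax()
        east_comp = run.Q[east].mean(axis=0).argmax()
        assert west_comp != east_comp

    def test_sample_permutation_permutes_q_rows(self, two_pop_sim):
        gm, _ = _ingroup(two_pop_sim)
        gm = gm.take_loci(np.arange(100))
        run = fit_admixture(gm, K=2, burn_in=50, n_reps=200, seed=4)
        perm = list(reversed(range(gm.n_samples)))
        gm_p = gm.take_samples([gm.samples[i] for i in perm])
        run_p = fit_admixture(gm_p, K=2, burn_in=50, n_reps=200, seed=4)
        # same sampler, same seed: rows follow the samples (up to column label swap)
        g_direct = similarity(run.Q[perm], run_p.Q)
        g_swapped = similarity(run.Q[perm], run_p.Q[:, ::-1])
        assert max(g_direct, g_swapped) > 0.9

    def test_sklearn_estimator_interface(self):
        from sklearn.base import clone

        model = AdmixtureModel(n_populations=2, burn_in=10, n_reps=20, random_state=0)
        params = model.get_params()
        assert params["n_populations"] == 2
        clone(model)  # sklearn contract: cloneable from get_params
        dosage = np.array([[0, 0, 2, 2], [2, 2, 0, 0], [0, 1, 1, 2]])
        fitted = model.fit(dosage)
        assert fitted.Q_.shape == (3, 2)
        assert fitted.P_.shape == (2, 4)


class TestAlignment:
    def test_swapped_columns_recovered(self, rng):
        q = rng.dirichlet((1, 1, 1), size=20)
        res = align_runs([q, q[:, [2, 0, 1]]])
        assert res.permutations[1] == (1, 2, 0)
        assert res.h_prime == pytest.approx(1.0)
        np.testing.assert_allclose(res.consensus_q, q)

    def test_similarity_matches_hand_arithmetic(self):
        q_a = np.array([[0.8, 0.2], [0.3, 0.7]])
        q_b = q_a.copy()
        q_b[1] = [0.7, 0.3]  # one row replaced by its complement
        # ||diff||_F = sqrt(0.4^2 + 0.4^2); G = 1 - that / sqrt(2*2)
        expected = 1.0 - math.sqrt(2 * 0.4**2) / math.sqrt(4.0)
        assert similarity(q_a, q_b) == pytest.approx(expected, abs=1e-12)

    def test_single_run_flagged(self, rng):
        q = rng.dirichlet((1, 1), size=5)
        res = align_runs([q])
        assert res.single_run and res.h_prime == 1.0

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="does not match"):
            align_runs([rng.dirichlet((1, 1), size=5), rng.dirichlet((1, 1), size=6)])

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_similarity_bounded(self, seed):
        rng = np.random.default_rng(seed)
        n, k = int(rng.integers(2, 12)), int(rng.integers(2, 5))
        res = align_runs([rng.dirichlet(np.ones(k), size=n) for _ in range(3)])
        assert 0.0 <= res.h_prime <= 1.0
        assert ((res.pairwise_g >= 0) & (res.pairwise_g <= 1)).all()


class TestEvanno:
    def test_hand_worked_example(self):
        # means -1000, -800, -790, -785 with sd 10 at every K
        def reps(mean):
            return [mean - 10 / math.sqrt(2), mean + 10 / math.sqrt(2)]

        res = evanno_delta_k({1: reps(-1000), 2: reps(-800), 3: reps(-790), 4: reps(-785)})
        tab = res.table.set_index("K")
        assert tab.loc[2, "delta_K"] == pytest.approx(19.0)
        assert tab.loc[3, "delta_K"] == pytest.approx(0.5)
        assert res.best_k == 2

    def test_linear_likelihood_gives_zero_delta_k(self):
        res = evanno_delta_k({k: [-100.0 * k + 1, -100.0 * k - 1] for k in range(1, 5)})
        assert (res.table["delta_K"].dropna() == 0).all()

    def test_zero_sd_warns_and_gives_inf(self):
        with pytest.warns(UserWarning, match="zero replicate"):
            res = evanno_delta_k({1: [-10, -10], 2: [-5, -5], 3: [-4.5, -4.5]})
        assert np.isinf(res.table.set_index("K").loc[2, "delta_K"])

    def test_requires_consecutive_ks(self):
        with pytest.raises(ValueError, match="consecutive"):
            evanno_delta_k({1: [0, 0], 3: [0, 0], 4: [0, 0]})


class TestAssignment:
    @pytest.mark.parametrize(
        "row, label",
        [((0.80, 0.20), "pop_1"), ((0.75, 0.25), "pop_1"), ((0.60, 0.40), "Mixed"),
         ((0.10, 0.90), "pop_2")],
    )
    def test_purity_rule(self, row, label):
        out = assign_populations(np.array([row]), threshold=0.75)
        assert out.loc[0, "label"] == label

    def test_threshold_validation(self):
        with pytest.raises(ValueError, match="threshold"):
            assign_populations(np.array([[0.5, 0.5]]), threshold=0.5)
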