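"""Variational inference engine: updates, ELBO, variants, projection."""

import numpy as np
import pytest

from microtensor import (
    BayesianTensorFactorization,
    LongitudinalTensor,
    reconstruct,
    rmse,
    simulate_tensor,
)
from microtensor.btf import FactorSet


def _random_tensor(shape, seed):
    rng = np.random.default_rng(seed)
    return LongitudinalTensor(np.abs(rng.standard_normal(shape)))


class TestReconstructRmse:
    def test_hand_multiplied_rank_one(self):
        H = np.array([[1.0]])
        M = np.array([[2.0, 3.0]])
        T = np.array([[4.0], [5.0]])
        out = reconstruct((H, M, T))
        np.testing.assert_array_equal(out, [[[8.0, 10.0], [12.0, 15.0]]])

    def test_zero_loadings_give_zero_tensor(self):
        out = reconstruct((np.ones((3, 2)), np.zeros((2, 4)), np.ones((5, 2))))
        assert not out.any()

    def test_matches_triple_loop_oracle(self, rng):
        H, M, T = rng.standard_normal((4, 3)), rng.standard_normal((3, 5)), rng.standard_normal((6, 3))
        fast = reconstruct((H, M, T))
        slow = np.zeros((4, 5, 6))
        for n in range(4):
            for l in range(5):
                for k in range(6):
                    slow[n, l, k] = sum(H[n, c] * M[c, l] * T[k, c] for c in range(3))
        np.testing.assert_allclose(fast, slow, atol=1e-12)

    def test_rmse_identical_zero_and_constant_shift(self):
        t = _random_tensor((3, 4, 2), 0)
        assert rmse(t, t.data) == 0.0
        assert rmse(t, t.data + 2.0) == pytest.approx(2.0)

    def test_rmse_matches_loop_oracle(self, rng):
        a = rng.standard_normal((3, 4, 2))
        b = rng.standard_normal((3, 4, 2))
        expected = np.sqrt(np.mean([(a[i] - b[i]) ** 2 for i in range(3)]))
        assert rmse(LongitudinalTensor(np.abs(a)), np.abs(a) - (a - b)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_rmse_empty_mask_errors(self):
        t = LongitudinalTensor(np.ones((2, 2, 2)), mask=np.zeros((2, 2, 2), bool))
        with pytest.raises(ValueError, match="mask"):
            rmse(t, np.ones((2, 2, 2)))

    def test_true_factors_reconstruct_noiseless_tensor_exactly(self):
        tensor, truth = simulate_tensor(
            N=6, L=10, K=4, C=2, noise_sd=0, seed=3, clip_negative=False
        )
        assert rmse(tensor, reconstruct((truth.H, truth.M, truth.T))) == 0.0


class TestInitialization:
    def _state(self, seed, tensor=None):
        tensor = tensor or _random_tensor((4, 6, 3), 0)
        model = BayesianTensorFactorization(n_modules_max=3, random_state=seed)
        return model._init_state(tensor, np.random.default_rng(seed))

    def test_same_seed_identical_states(self):
        a, b = self._state(7), self._state(7)
        np.testing.assert_array_equal(a.mH, b.mH)
        np.testing.assert_array_equal(a.mW, b.mW)
        np.testing.assert_array_equal(a.mT, b.mT)

    def test_different_seeds_differ(self):
        assert not np.array_equal(self._state(1).mH, self._state(2).mH)

    def test_inclusion_probabilities_start_at_half(self):
        st = self._state(0)
        assert (st.g == 0.5).all()

    def test_precisions_start_at_prior(self):
        st = self._state(0)
        assert (st.lam_sh == 1e-3).all() and (st.lam_ra == 1e-3).all()


class TestElboMonotonicity:
    @pytest.mark.parametrize(
        "variant", ["visit_correlated", "visit_uncorrelated", "matrix_2d"]
    )
    def test_elbo_never_decreases_across_sweeps(self, variant):
        tensor = _random_tensor((5, 6, 4), 42)
        model = BayesianTensorFactorization(
            n_modules_max=4, variant=variant, max_iter=30, n_warmup=5, random_state=0
        ).fit(tensor)
        trace = np.array(model.elbo_trace_)
        drops = np.diff(trace) < -1e-6 * np.abs(trace[:-1])
        assert not drops.any(), f"ELBO decreased at sweeps {np.flatnonzero(drops)}"

    def test_elbo_monotone_with_missing_visits(self):
        tensor = _random_tensor((6, 5, 4), 1)
        mask = tensor.mask.copy()
        mask[0, :, 2:] = False  # subject 0 observed at 2 of 4 visits
        mask[3, :, 3:] = False
        model = BayesianTensorFactorization(
            n_modules_max=3, max_iter=25, n_warmup=5, random_state=0
        ).fit(tensor, mask=mask)
        trace = np.array(model.elbo_trace_)
        assert (np.diff(trace) >= -1e-6 * np.abs(trace[:-1])).all()
        # fully masked (subject, visit) noise precisions stay at their prior
        st = model.state_
        assert st.lam_sh[0, 3] == pytest.approx(1e-3)
        assert st.lam_ra[0, 3] == pytest.approx(1e-3)


class TestUpdateOracles:
    def test_h_update_equals_ridge_closed_form(self, rng):
        """With all indicators clamped to 1 and a single module, the H update
        is exactly the Bayesian ridge-regression posterior."""
        tensor = _random_tensor((3, 4, 2), 9)
        model = BayesianTensorFactorization(n_modules_max=1, random_state=0)
        st = model._init_state(tensor, np.random.default_rng(0))
        st.clamp_s = True
        st.g[:] = 1.0
        st.update_H()
        EM, EM2, ET2, Elam = st.EM, st.EM2, st.ET2, st.Elam
        for n in range(3):
            prec = 1.0
            lin = 0.0
            for l in range(4):
                for k in range(2):
                    prec += Elam[n, k] * EM2[0, l] * ET2[k, 0]
                    lin += Elam[n, k] * tensor.data[n, l, k] * EM[0, l] * st.mT[k, 0]
            assert st.vH[n, 0] == pytest.approx(1.0 / prec, rel=1e-10)
            assert st.mH[n, 0] == pytest.approx(lin / prec, rel=1e-10)

    def test_expected_squared_residual_matches_loop(self, rng):
        tensor = _random_tensor((3, 4, 2), 5)
        model = BayesianTensorFactorization(n_modules_max=2, random_state=1)
        st = model._init_state(tensor, np.random.default_rng(1))
        for _ in range(3):
            st.sweep()
        S = st._sq_resid_stats()
        EM, EM2, ET2, EH2 = st.EM, st.EM2, st.ET2, st.EH2
        EMM = st._emm()
        for n in range(3):
            for k in range(2):
                acc = 0.0
                for l in range(4):
                    mean = sum(st.mH[n, c] * EM[c, l] * st.mT[k, c] for c in range(2))
                    second = 0.0
                    for c in range(2):
                        for d in range(2):
                            hh = EH2[n, c] if c == d else st.mH[n, c] * st.mH[n, d]
                            tt = ET2[k, c] if c == d else st.mT[k, c] * st.mT[k, d]
                            second += hh * tt * EMM[c, d, l]
                    acc += tensor.data[n, l, k] ** 2 - 2 * tensor.data[n, l, k] * mean + second
                assert S[n, k] == pytest.approx(acc, rel=1e-8)


class TestDegenerateInputs:
    def test_zero_tensor_yields_no_modules(self):
        tensor = LongitudinalTensor(np.zeros((5, 6, 3)))
        model = BayesianTensorFactorization(
            n_modules_max=4, max_iter=30, n_warmup=2, random_state=0
        ).fit(tensor)
        assert model.n_modules_ == 0
        assert model.rmse_ == 0.0

    def test_zero_tensor_slab_means_collapse(self):
        tensor = LongitudinalTensor(np.zeros((4, 5, 3)))
        model = BayesianTensorFactorization(n_modules_max=3, random_state=0)
        st = model._init_state(tensor, np.random.default_rng(0))
        norms = []
        for _ in range(5):
            st.sweep()
            norms.append(np.abs(st.mW).max())
        assert norms[0] < 1e-8 or np.all(np.diff(norms) <= 1e-12)

    def test_all_masked_tensor_rejected(self):
        t = LongitudinalTensor(np.ones((2, 3, 2)), mask=np.zeros((2, 3, 2), bool))
        with pytest.raises(ValueError, match="no observed"):
            BayesianTensorFactorization(n_modules_max=2).fit(t)

    def test_bad_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            BayesianTensorFactorization(n_modules_max=0).fit(np.ones((2, 2, 2)))
        with pytest.raises(ValueError):
            BayesianTensorFactorization(noise_shape=-1.0).fit(np.ones((2, 2, 2)))
        with pytest.raises(ValueError, match="variant"):
            BayesianTensorFactorization(variant="nope").fit(np.ones((2, 2, 2)))


class TestVariants:
    def test_single_visit_limit_equates_chain_and_iid_priors(self):
        """With K=1 the random-walk prior degenerates to the i.i.d. prior, so
        both variants must produce identical posteriors under the same seed."""
        tensor = _random_tensor((8, 10, 1), 3)
        fits = {}
        for v in ("visit_correlated", "visit_uncorrelated"):
            fits[v] = BayesianTensorFactorization(
                n_modules_max=4, variant=v, max_iter=40, n_warmup=5, random_state=5
            ).fit(tensor)
        np.testing.assert_allclose(
            fits["visit_correlated"].subject_factors_,
            fits["visit_uncorrelated"].subject_factors_,
            atol=1e-6,
        )

    def test_matrix_variant_elbo_invariant_to_sample_permutation(self):
        tensor = _random_tensor((4, 6, 3), 8)
        model = BayesianTensorFactorization(
            n_modules_max=3, variant="matrix_2d", max_iter=10, n_warmup=2, random_state=0
        ).fit(tensor)
        st = model.state_
        base = st.elbo()
        perm = np.random.default_rng(0).permutation(st.N)
        for name in ("X", "m2", "t1", "mH", "vH", "lam_sh", "lam_ra"):
            setattr(st, name, getattr(st, name)[perm])
        assert st.elbo() == pytest.approx(base, rel=1e-10)

    def test_sparser_inclusion_prior_never_adds_members(self):
        tensor, _ = simulate_tensor(N=15, L=20, K=5, C=2, seed=4)
        counts = []
        for b in (1.0, 7.0, 30.0):
            m = BayesianTensorFactorization(
                n_modules_max=4, inclusion_b=b, max_iter=150, random_state=2
            ).fit(tensor)
            counts.append(int((m.pip_ > 0.5).sum()))
        assert counts[0] >= counts[1] >= counts[2]


class TestRecovery:
    def test_noiseless_rank2_exact_recovery(self):
        tensor, truth = simulate_tensor(
            N=20, L=30, K=8, C=2, noise_sd=0, seed=5, clip_negative=False
        )
        model = BayesianTensorFactorization(
            n_modules_max=10, max_iter=400, random_state=0
        ).fit(tensor)
        assert model.rmse_ <= 1e-2
        assert model.n_modules_ == 2

    def test_fit_accepts_raw_array(self):
        tensor, _ = simulate_tensor(N=8, L=10, K=4, C=2, seed=6)
        a = BayesianTensorFactorization(n_modules_max=3, max_iter=30, random_state=0).fit(tensor)
        b = BayesianTensorFactorization(n_modules_max=3, max_iter=30, random_state=0).fit(tensor.data)
        np.testing.assert_allclose(a.subject_factors_, b.subject_factors_)


class TestProjection:
    def test_self_projection_correlates_with_reference(self, case_control):
        tensor, labels, truth, fit = case_control
        Hp, Tp = fit.project(tensor)
        for c in fit.active_modules_:
            r = np.corrcoef(fit.subject_factors_[:, c], Hp[:, c])[0, 1]
            assert r >= 0.9, f"module {c}: correlation {r:.3f}"

    def test_single_subject_projects_nearest_its_reference_row(self, case_control):
        tensor, labels, truth, fit = case_control
        n0 = 3
        sub = LongitudinalTensor(
            tensor.data[n0 : n0 + 1], subjects=["probe"], taxa=tensor.taxa
        )
        Hp, _ = fit.project(sub)
        act = fit.active_modules_  # inactive columns carry no signal
        d = np.linalg.norm(fit.subject_factors_[:, act] - Hp[0, act], axis=1)
        assert d.argmin() == n0

    def test_zero_loadings_give_zero_activities(self, case_control):
        tensor, _, _, fit = case_control
        silent = BayesianTensorFactorization(**fit.get_params())
        # clone the fit but null out the loadings: no signal to project onto
        for attr in (
            "subject_factors_", "taxon_factors_", "visit_factors_", "pip_",
            "active_modules_", "n_modules_", "elbo_trace_", "elbo_", "n_iter_",
            "rmse_", "noise_precision_", "temporal_precision_", "slab_precision_",
            "taxa_", "subjects_", "visits_", "state_",
        ):
            setattr(silent, attr, getattr(fit, attr))
        silent.taxon_factors_ = np.zeros_like(fit.taxon_factors_)
        Hp, _ = silent.project(tensor, max_iter=30)
        assert np.abs(Hp).max() < 1e-6

    def test_disjoint_taxa_rejected(self, case_control):
        tensor, _, _, fit = case_control
        other = LongitudinalTensor(
            tensor.data[:, :5, :], taxa=[f"alien{i}" for i in range(5)]
        )
        with pytest.raises(ValueError, match="shared"):
            fit.project(other)


def test_factor_set_shapes(planted_fit):
    fs = planted_fit.factors_
    assert isinstance(fs, FactorSet)
    N, C = fs.H.shape
    C2, L = fs.M.shape
    K, C3 = fs.T.shape
    assert C == C2 == C3
    assert fs.lam.shape == (N, K)
    assert (fs.lam > 0).all() and (fs.Lam > 0).all() and (fs.beta > 0).all()
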