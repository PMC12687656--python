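"""NNMF factorization, VAF diagnostics and dimensionality selection."""

import numpy as np
import pytest

from slipsynergy import synergy, synthetic
from slipsynergy.synergy import (
    DimensionalityError,
    nnmf,
    select_dimensionality,
    unscale_and_normalize,
    vaf_global,
    vaf_muscle,
)


def rank1_matrix():
    w = np.array([1.0, 2, 0, 0, 0, 0, 0, 0])[:, None]
    c = np.array([[1.0, 2, 3, 4]])
    return w @ c


class TestNnmf:
    def test_exact_rank1_recovered(self):
        s = nnmf(rank1_matrix(), k=1, seed=0)
        assert s.vaf_global >= 99.9

    def test_factors_non_negative(self):
        rng = np.random.default_rng(3)
        s = nnmf(np.abs(rng.normal(size=(8, 40))), k=3, seed=1)
        assert s.W.min() >= 0 and s.C.min() >= 0

    def test_same_seed_bitwise_identical(self):
        rng = np.random.default_rng(4)
        m = np.abs(rng.normal(size=(8, 40)))
        a = nnmf(m, k=3, seed=9)
        b = nnmf(m, k=3, seed=9)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.C, b.C)

    def test_objective_monotone_under_updates(self):
        rng = np.random.default_rng(5)
        m = np.abs(rng.normal(size=(8, 60)))
        # check_monotone raises if any multiplicative update increases loss
        nnmf(m, k=4, seed=2, check_monotone=True)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            nnmf(np.zeros((8, 10)), k=1, seed=0)

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            nnmf(np.ones((8, 4)), k=5, seed=0)

    def test_matches_sklearn_objective(self):
        """Independent cross-check: residual close to sklearn's NMF."""
        from sklearn.decomposition import NMF
        rng = np.random.default_rng(6)
        m = np.abs(rng.normal(size=(8, 50)))
        ours = nnmf(m, k=3, restarts=20, seed=0)
        sk = NMF(n_components=3, init="random", max_iter=2000, tol=1e-9,
                 random_state=0)
        wk = sk.fit_transform(m)
        resid_sk = np.sum((m - wk @ sk.components_) ** 2)
        assert ours.objective <= resid_sk * 1.05


class TestVaf:
    def test_exact_reconstruction_is_100(self):
        m = rank1_matrix()
        s = nnmf(m, k=1, seed=0)
        assert vaf_global(m, s) == pytest.approx(100.0, abs=1e-6)
        # zero rows perfectly reconstructed count as fully explained
        np.testing.assert_allclose(s.vaf_muscle, 100.0, atol=1e-6)

    def test_standalone_vaf_muscle(self):
        rng = np.random.default_rng(7)
        m = np.abs(rng.normal(size=(8, 30))) + 0.1
        s = nnmf(m, k=3, seed=0)
        np.testing.assert_allclose(vaf_muscle(m, s), s.vaf_muscle, atol=1e-9)
        m_zero = m.copy()
        m_zero[2] = 0.0
        with pytest.raises(ValueError, match="zero"):
            vaf_muscle(m_zero, s)

    def test_hand_arithmetic_global(self):
        m = np.array([[1.0, 1], [1, 1]])
        recon = np.array([[1.0, 1], [1, 0]])
        assert synergy._vaf_pct(m, recon) == pytest.approx(75.0)

    def test_zero_reconstruction_is_zero(self):
        m = np.array([[1.0, 1], [1, 1]])
        assert synergy._vaf_pct(m, np.zeros((2, 2))) == pytest.approx(0.0)

    def test_hand_arithmetic_muscle(self):
        row = np.array([[3.0, 4]])
        recon = np.array([[3.0, 0]])
        assert synergy._vaf_pct(row, recon) == pytest.approx(36.0)

    def test_mean_muscle_vaf_differs_from_global(self):
        # rows of very unequal energy: global VAF weights them by energy
        m = np.array([[10.0, 10], [1, 1]] + [[1, 1]] * 6)
        recon = m.copy()
        recon[1] = 0  # second muscle entirely missed
        g = synergy._vaf_pct(m, recon)
        per = [synergy._vaf_pct(m[i:i + 1], recon[i:i + 1]) for i in range(8)]
        assert abs(np.mean(per) - g) > 5.0


class TestSelectDimensionality:
    def test_rank1_selects_one(self):
        s = select_dimensionality(rank1_matrix(), k_max=4, seed=0)
        assert s.k == 1

    def test_planted_k5_recovered(self, ground_truth, small_session):
        from slipsynergy import pipeline
        from slipsynergy.io_model import PipelineConfig
        session, _, _ = small_session
        ps = pipeline.extract_participant_stage(session, "early", PipelineConfig())
        assert ps.synergies.k == 5

    def test_unreachable_criteria_raise_with_curve(self):
        rng = np.random.default_rng(8)
        m = np.abs(rng.normal(size=(8, 200)))  # unstructured noise
        with pytest.raises(DimensionalityError) as err:
            select_dimensionality(m, k_max=2, seed=0)
        assert set(err.value.vaf_curve) == {1, 2}

    def test_vaf_nondecreasing_in_k(self, ground_truth):
        sc = synthetic.TrialScript("S1", 2.5, 2.75, 2.93, 0.17)
        emg = synthetic.synthesize_emg(ground_truth, sc, seed=11)
        from slipsynergy import preprocess
        env = preprocess.envelope(emg)
        win = preprocess.window(env, sc.bon_s, sc.td_s)
        m = preprocess.scale_unit_variance(
            preprocess.normalize_max(preprocess.bin_average(win)))
        vafs = [nnmf(m, k, restarts=20, seed=k).vaf_global for k in range(1, 7)]
        assert np.all(np.diff(vafs) > -0.5)


class TestParameterRecovery:
    def test_planted_synergy_vectors_recovered(self):
        """Planted K=4, 10% envelope noise: matched cosine >= 0.95 mean."""
        rng_master = np.random.default_rng(2024)
        cosines = []
        for _ in range(20):
            seed = int(rng_master.integers(2 ** 31))
            rng = np.random.default_rng(seed)
            # sparse planted vectors: dense NMF is not identifiable
            w_true = rng.uniform(0, 0.6, size=(8, 4))
            w_true[rng.permutation(8)[:3], :] = 0.0
            for j, dom in enumerate(rng.permutation(8)[:4]):
                w_true[dom, j] = 1.0
            t = np.linspace(0, 100, 100)
            c_true = np.vstack([
                np.exp(-0.5 * ((t - p) / 7.0) ** 2)
                for p in (20, 40, 60, 80)
            ])
            m = w_true @ c_true
            m = m + rng.normal(0, 0.10 * m.mean(), size=m.shape)
            m = np.clip(m, 0, None)
            s = nnmf(m, k=4, restarts=20, seed=seed)
            w_hat = s.W / np.linalg.norm(s.W, axis=0)
            w_ref = w_true / np.linalg.norm(w_true, axis=0)
            sim = w_ref.T @ w_hat
            used = set()
            for _ in range(4):
                i, j = np.unravel_index(np.argmax(sim), sim.shape)
                cosines.append(sim[i, j])
                sim[i, :] = -1
                sim[:, j] = -1
        assert np.mean(cosines) >= 0.95


class TestUnscale:
    def _fitted(self):
        rng = np.random.default_rng(9)
        m = np.abs(rng.normal(size=(8, 50)))
        return m, nnmf(m, k=3, seed=0)

    def test_reconstruction_invariant(self):
        _, s = self._fitted()
        scales = np.linspace(0.5, 2.0, 8)
        u = unscale_and_normalize(s, scales)
        np.testing.assert_allclose(u.W @ u.C, (s.W * scales[:, None]) @ s.C,
                                   atol=1e-12)

    def test_unit_scales_only_normalize(self):
        _, s = self._fitted()
        u = unscale_and_normalize(s, np.ones(8))
        np.testing.assert_allclose(u.W.max(axis=0), 1.0)
        np.testing.assert_allclose(u.W @ u.C, s.W @ s.C, atol=1e-12)

    def test_round_trip_of_row_scaling(self):
        """Scaling rows to unit variance then unscaling restores W's scale."""
        rng = np.random.default_rng(10)
        from slipsynergy import preprocess
        from conftest import make_emg
        x = np.abs(rng.normal(size=(8, 300))) * np.linspace(0.5, 4, 8)[:, None]
        m = preprocess.bin_average(make_emg(x))
        scaled = preprocess.scale_unit_variance(m)
        s = nnmf(scaled, k=3, restarts=10, seed=0)
        u = unscale_and_normalize(s, scaled.unit_var_scales)
        recon_scaled = (s.W @ s.C) * scaled.unit_var_scales[:, None]
        np.testing.assert_allclose(u.W @ u.C, recon_scaled, atol=1e-9)

    def test_nonpositive_scale_rejected(self):
        _, s = self._fitted()
        with pytest.raises(ValueError):
            unscale_and_normalize(s, np.zeros(8))
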