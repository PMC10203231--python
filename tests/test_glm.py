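"""Mass-univariate OLS engine: estimates, t/p maps, PSC, thresholding."""

import numpy as np
import pytest
from scipy import stats as st

from cvrkit.glm import (
    DesignMatrix,
    contrast_t,
    fit_glm,
    make_design,
    percent_signal_change,
    threshold_map,
)
from cvrkit.kernels import Regressor, build_regressor, canonical_hrf
from cvrkit.runs import BoldRun


def _run_from_matrix(Y):
    """Wrap a (T, V) data matrix as a BoldRun with a flat mask."""
    T, V = Y.shape
    return BoldRun(data=Y.T.reshape(V, 1, 1, T), tr=2.0, mask=np.ones((V, 1, 1), bool))


def _design(X, names=None):
    names = names or ["constant"] + [f"x{j}" for j in range(1, X.shape[1])]
    return DesignMatrix(values=X, names=names, tr=2.0)


class TestFitGlm:
    def test_exact_fit_recovers_construction(self, rng):
        X = np.column_stack([np.ones(12), rng.normal(size=(12, 2))])
        B = rng.normal(size=(3, 5))
        Y = X @ B
        res = fit_glm(_run_from_matrix(Y), _design(X))
        np.testing.assert_allclose(res.betas.T, B, atol=1e-10)
        assert np.all(res.sigma2 < 1e-20)

    def test_orthonormal_design_betas_are_inner_products(self):
        T = 16
        Q, _ = np.linalg.qr(np.random.default_rng(3).normal(size=(T, 3)))
        Q[:, 0] = 1.0 / np.sqrt(T)  # orthonormal constant column
        Q[:, 1:], _ = np.linalg.qr(Q[:, 1:] - Q[:, [0]] * (Q[:, [0]].T @ Q[:, 1:]))
        y = np.random.default_rng(4).normal(size=(T, 2))
        res = fit_glm(_run_from_matrix(y), _design(Q))
        np.testing.assert_allclose(res.betas.T, Q.T @ y, atol=1e-10)

    def test_toy_problem_matches_hand_normal_equations(self):
        # 5 volumes, 2 columns; oracle computed by explicit matrix algebra
        X = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0], [1.0, 3.0], [1.0, 4.0]])
        y = np.array([1.1, 1.9, 3.2, 3.8, 5.1])
        b_oracle = np.linalg.solve(X.T @ X, X.T @ y)
        res = fit_glm(_run_from_matrix(y[:, None]), _design(X))
        np.testing.assert_allclose(res.betas[0], b_oracle, atol=1e-12)
        assert res.dof == 3

    def test_matches_normal_equation_oracle_on_random_problems(self, rng):
        for _ in range(30):
            T = int(rng.integers(8, 21))
            k = int(rng.integers(2, 6))
            X = rng.normal(size=(T, k))
            X[:, 0] = 1.0
            Y = rng.normal(size=(T, 3))
            res = fit_glm(_run_from_matrix(Y), _design(X))
            oracle = np.linalg.solve(X.T @ X, X.T @ Y)
            scale = max(np.abs(oracle).max(), 1e-12)
            assert np.abs(res.betas.T - oracle).max() / scale < 1e-10

    def test_rank_deficiency_names_columns(self):
        X = np.column_stack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError, match="rank deficient"):
            fit_glm(_run_from_matrix(np.zeros((10, 1))), _design(X))

    def test_row_mismatch_rejected(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="rows"):
            fit_glm(_run_from_matrix(np.zeros((12, 1))), _design(X))


class TestDesignMatrix:
    def test_requires_unique_names_and_one_constant(self):
        X = np.ones((5, 2))
        with pytest.raises(ValueError, match="constant"):
            DesignMatrix(values=X, names=["a", "b"], tr=2.0)
        with pytest.raises(ValueError, match="unique"):
            DesignMatrix(values=X, names=["constant", "constant"], tr=2.0)

    def test_make_design_nuisance_sets(self):
        reg = Regressor(name="task", samples=np.arange(20.0), peak_height=1.0)
        d_lin = make_design([reg], 20, 2.0, drift="linear")
        assert d_lin.names == ["task", "constant", "drift_linear"]
        d_cos = make_design([reg], 20, 2.0, drift="cosine", highpass_cutoff=20.0)
        assert sum(n.startswith("drift_cos") for n in d_cos.names) == 4
        motion = np.random.default_rng(0).normal(size=(20, 6))
        d_mot = make_design([reg], 20, 2.0, motion=motion)
        assert sum(n.startswith("motion") for n in d_mot.names) == 6


class TestContrastT:
    def _toy(self):
        X = np.array([[1.0, 0.2], [1.0, 0.9], [1.0, 1.7], [1.0, 2.2], [1.0, 3.4], [1.0, 4.1]])
        y = np.array([0.7, 1.6, 2.2, 3.4, 4.9, 5.4])
        res = fit_glm(_run_from_matrix(y[:, None]), _design(X))
        return X, y, res

    def test_zero_contrast_gives_zero_t(self):
        _, _, res = self._toy()
        stat = contrast_t(res, [0.0, 0.0])
        assert stat.t[0] == 0.0

    def test_matches_textbook_formula(self):
        # scalar oracle: t = c'b / sqrt(s2 * c'(X'X)^-1 c)
        X, y, res = self._toy()
        b = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ b
        s2 = resid @ resid / (len(y) - 2)
        c = np.array([0.0, 1.0])
        t_oracle = (c @ b) / np.sqrt(s2 * c @ np.linalg.inv(X.T @ X) @ c)
        stat = contrast_t(res, c)
        assert stat.t[0] == pytest.approx(t_oracle, rel=1e-12)
        assert stat.p[0] == pytest.approx(st.t.sf(t_oracle, 4), rel=1e-12)

    def test_scale_invariance(self):
        X, y, res = self._toy()
        res2 = fit_glm(_run_from_matrix(2 * y[:, None]), _design(2 * X))
        t1 = contrast_t(res, [0, 1.0]).t[0]
        t2 = contrast_t(res2, [0, 1.0]).t[0]
        assert t1 == pytest.approx(t2, rel=1e-10)

    def test_p_uniform_under_null(self):
        # Kolmogorov-Smirnov on 5000 pure-noise voxels, alpha = 0.01
        rng = np.random.default_rng(77)
        T, V = 60, 5000
        X = np.column_stack([np.ones(T), rng.normal(size=T)])
        Y = rng.normal(size=(T, V))
        res = fit_glm(_run_from_matrix(Y), _design(X))
        stat = contrast_t(res, [0.0, 1.0])
        ks = st.kstest(stat.p, "uniform")
        assert ks.pvalue > 0.01

    def test_p_monotone_in_t(self):
        _, _, res = self._toy()
        stat = contrast_t(res, [0.0, 1.0])
        ts = np.linspace(-3, 3, 11)
        ps = st.t.sf(ts, stat.dof)
        assert np.all(np.diff(ps) < 0)


class TestPercentSignalChange:
    def test_recovers_injected_amplitude(self, small_atlas, bh_paradigm, truth_factory):
        # noiseless run with known parcel amplitudes -> PSC equal by construction
        from cvrkit.phantom import simulate_run
        from cvrkit.kernels import ramp_regressor, respiratory_response_function

        truth = truth_factory(lag_choices=(0.0,))
        run = simulate_run(small_atlas, truth, bh_paradigm, subject=0, noise_sd=0.0, seed=0)
        rrf = respiratory_response_function(run.tr / 16)
        ramp = ramp_regressor(bh_paradigm, run.tr / 16)
        reg = build_regressor(ramp, rrf, run.n_volumes, run.tr, name="bh")
        design = make_design([reg], run.n_volumes, run.tr)
        res = fit_glm(run, design)
        psc = percent_signal_change(res, design.contrast_vector({"bh": 1.0}))
        vol = psc.volume()
        for lab in small_atlas.label_table:
            injected = truth.bh_psc_true[lab - 1, 0]
            est = np.nanmean(vol[small_atlas.label_volume == lab])
            assert est == pytest.approx(injected, rel=0.01)

    def test_simple_arithmetic(self):
        # baseline 100, effect 1.5 at unit peak height -> psc = 1.5
        T = 24
        x = np.sin(np.linspace(0, 3 * np.pi, T))
        x /= np.abs(x).max()
        y = 100.0 + 1.5 * x
        X = np.column_stack([x, np.ones(T)])
        design = DesignMatrix(
            values=X,
            names=["task", "constant"],
            tr=2.0,
            regressors={"task": Regressor(name="task", samples=x, peak_height=1.0, highres=x, highres_dt=2.0)},
        )
        res = fit_glm(_run_from_matrix(y[:, None]), design)
        psc = percent_signal_change(res, design.contrast_vector({"task": 1.0}))
        assert psc.psc[0] == pytest.approx(1.5, rel=1e-10)

    def test_null_contrast_small_on_noise(self, rng):
        T, V = 80, 50
        x = rng.normal(size=T)
        X = np.column_stack([x, np.ones(T)])
        design = DesignMatrix(
            values=X,
            names=["task", "constant"],
            tr=2.0,
            regressors={"task": Regressor(name="task", samples=x, peak_height=float(np.abs(x).max()), highres=x, highres_dt=2.0)},
        )
        Y = 100.0 + rng.normal(size=(T, V))
        res = fit_glm(_run_from_matrix(Y), design)
        psc = percent_signal_change(res, design.contrast_vector({"task": 1.0}))
        assert np.abs(psc.psc.mean()) < 3 * psc.psc.std() / np.sqrt(V)

    def test_nonpositive_baseline_masked(self):
        T = 10
        x = np.sin(np.arange(T))
        X = np.column_stack([x, np.ones(T)])
        design = DesignMatrix(
            values=X, names=["task", "constant"], tr=2.0,
            regressors={"task": Regressor(name="task", samples=x, peak_height=1.0, highres=x, highres_dt=2.0)},
        )
        Y = np.column_stack([100 + x, -5 + 0 * x])  # second voxel negative baseline
        res = fit_glm(_run_from_matrix(Y), design)
        psc = percent_signal_change(res, design.contrast_vector({"task": 1.0}))
        assert psc.psc.size == 1
        assert int(psc.mask.sum()) == 1


class TestThresholdMap:
    def _maps(self, rng, frac_active=0.3, snr=8.0, T=80, V=1000):
        x = np.sin(np.linspace(0, 8 * np.pi, T))
        X = np.column_stack([x, np.ones(T)])
        design = DesignMatrix(
            values=X, names=["task", "constant"], tr=2.0,
            regressors={"task": Regressor(name="task", samples=x, peak_height=1.0, highres=x, highres_dt=2.0)},
        )
        active = np.zeros(V, bool)
        active[: int(frac_active * V)] = True
        Y = 100.0 + rng.normal(size=(T, V))
        Y[:, active] += snr * x[:, None]
        res = fit_glm(_run_from_matrix(Y), design)
        w = design.contrast_vector({"task": 1.0})
        return contrast_t(res, w), percent_signal_change(res, w), active

    def test_alpha_one_keeps_all(self, rng):
        stat, psc, _ = self._maps(rng)
        out, n = threshold_map(stat, psc, alpha=1.0)
        assert n == int(psc.mask.sum())

    def test_tiny_alpha_keeps_none(self, rng):
        stat, psc, _ = self._maps(rng, snr=0.0)
        out, n = threshold_map(stat, psc, alpha=1e-12)
        assert n == 0

    def test_recall_and_false_positives_with_known_truth(self, rng):
        stat, psc, active = self._maps(rng, frac_active=0.3, snr=2.0)
        out, n = threshold_map(stat, psc, alpha=0.001)
        kept = out.mask.reshape(-1)
        recall = kept[active.nonzero()[0]].mean()
        fpr = kept[(~active).nonzero()[0]].mean()
        assert recall >= 0.95
        assert fpr <= 0.005

    def test_alpha_bounds(self, rng):
        stat, psc, _ = self._maps(rng)
        with pytest.raises(ValueError):
            threshold_map(stat, psc, alpha=0.0)
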