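"""Threshold gradient descent: masks, sparsity, and the two fitters."""

import numpy as np
import pytest
from lifelines import CoxPHFitter

from tgdrsurv import (
    SimulationDesign,
    TGDRConfig,
    fit_cnt,
    fit_ct,
    generate_replicate,
    importance,
    threshold_indicators,
)
from tgdrsurv.network import GradientSet
from tgdrsurv.survival import CoxPartialLikelihood

from conftest import random_survival_data


def make_grads(dW1, dW2):
    dW1 = np.atleast_2d(np.asarray(dW1, dtype=float))
    return GradientSet(dW1=dW1, dW2=np.asarray(dW2, dtype=float),
                       db=np.zeros(dW1.shape[0]))


class TestThresholdIndicators:
    def test_tau_zero_passes_everything(self, rng):
        g = make_grads(rng.standard_normal((3, 5)), rng.standard_normal(3))
        masks = threshold_indicators(g, 0.0)
        assert masks.L1.all() and masks.L2.all()

    def test_tau_one_keeps_only_maxima(self):
        g = make_grads([[1.0, -3.0, 2.0], [0.5, 0.1, -0.2]], [2.0, -5.0])
        masks = threshold_indicators(g, 1.0)
        np.testing.assert_array_equal(masks.L2, [0, 1])
        np.testing.assert_array_equal(masks.L1, [[0, 1, 0], [1, 0, 0]])

    def test_hand_computed_example(self):
        masks = threshold_indicators(make_grads([[0.0]], [0.5, -1.0, 0.2]), 0.5)
        np.testing.assert_array_equal(masks.L2, [1, 1, 0])

    def test_row_wise_thresholding(self):
        # row 2's small gradients are compared to row 2's max only
        g = make_grads([[10.0, 1.0], [0.02, 0.01]], [1.0])
        masks = threshold_indicators(g, 0.9)
        np.testing.assert_array_equal(masks.L1, [[1, 0], [1, 0]])

    def test_invalid_tau_raises(self):
        with pytest.raises(ValueError, match="tau"):
            threshold_indicators(make_grads([[1.0]], [1.0]), 1.5)


def mirror_fit_cnt(data, config, record_fired=False):
    """Independent re-implementation of the CNT update loop (float32),
    optionally recording which entries ever passed the threshold."""
    rng = np.random.default_rng(config.seed)
    Z = data.Z.astype(np.float32)
    W1 = np.zeros((config.h, data.n_features), dtype=np.float32)
    W2 = np.zeros(config.h, dtype=np.float32)
    b = rng.normal(0.0, 0.1, size=config.h).astype(np.float32)
    plik = CoxPartialLikelihood(data)
    fired_W1 = np.zeros_like(W1, dtype=bool)
    fired_W2 = np.zeros_like(W2, dtype=bool)
    for k in range(config.K):
        A = np.tanh(Z @ W1.T + b)
        theta = A @ W2
        g = plik.gradient(theta.astype(float)).astype(np.float32)
        dW2 = A.T @ g
        dH = (g[:, None] * W2[None, :]) * (1.0 - A * A)
        dW1 = dH.T @ Z
        db = dH.sum(axis=0)
        if record_fired:
            masks = threshold_indicators(GradientSet(dW1, dW2, db), config.tau)
            L1 = masks.L1.astype(np.float32)
            L2 = masks.L2.astype(np.float32)
        else:  # unthresholded ascent: the tau=0 reference
            L1 = np.ones_like(dW1)
            L2 = np.ones_like(dW2)
        # an entry only moves when its indicator fires AND its gradient
        # is nonzero (all-zero rows yield all-ones masks but zero updates)
        fired_W1 |= (L1 > 0) & (dW1 != 0)
        fired_W2 |= (L2 > 0) & (dW2 != 0)
        alpha = np.float32(config.alpha0 * config.eta**k)
        W2 += alpha * (L2 * dW2)
        W1 += alpha * (L1 * dW1)
        b += alpha * db
    return W1.astype(float), W2.astype(float), b.astype(float), fired_W1, fired_W2


class TestFitCnt:
    def test_zero_iterations_leave_zero_weights(self, rng):
        data = random_survival_data(rng, n=20, p=4)
        fit = fit_cnt(data, TGDRConfig(tau=0.5, K=0, h=3, seed=1))
        np.testing.assert_array_equal(fit.params.W1, 0.0)
        np.testing.assert_array_equal(fit.params.W2, 0.0)
        assert importance(fit.params).selected.sum() == 0

    def test_tau_zero_equals_unthresholded_ascent(self, rng):
        """With tau=0 the masks are inert: trajectory is bit-identical to
        plain gradient ascent with the same seed and schedule."""
        data = random_survival_data(rng, n=30, p=5)
        config = TGDRConfig(tau=0.0, K=40, h=3, seed=11)
        fit = fit_cnt(data, config)
        W1, W2, b, *_ = mirror_fit_cnt(data, config, record_fired=False)
        np.testing.assert_array_equal(fit.params.W1, W1)
        np.testing.assert_array_equal(fit.params.W2, W2)
        np.testing.assert_array_equal(fit.params.b, b)

    def test_never_updated_weights_are_exact_zeros(self, rng):
        """Entries whose indicator never fired end bit-exactly zero."""
        data = random_survival_data(rng, n=40, p=40)
        config = TGDRConfig(tau=0.95, K=30, h=4, seed=2)
        fit = fit_cnt(data, config)
        W1, W2, _, fired_W1, fired_W2 = mirror_fit_cnt(
            data, config, record_fired=True
        )
        np.testing.assert_array_equal(fit.params.W1, W1)
        assert np.all(fit.params.W1[~fired_W1] == 0.0)
        assert np.all(fit.params.W2[~fired_W2] == 0.0)
        # thresholding must actually have suppressed something here
        assert not fired_W1.all()

    def test_smaller_tau_selects_no_fewer_variables(self, rng):
        data = random_survival_data(rng, n=60, p=15)
        counts = {}
        for tau in (0.3, 0.9):
            fit = fit_cnt(data, TGDRConfig(tau=tau, K=80, h=4, seed=3))
            counts[tau] = importance(fit.params).selected.sum()
        assert counts[0.3] >= counts[0.9]

    def test_bit_reproducible(self, rng):
        data = random_survival_data(rng, n=25, p=6)
        config = TGDRConfig(tau=0.8, K=30, h=3, seed=9)
        a, b_ = fit_cnt(data, config), fit_cnt(data, config)
        np.testing.assert_array_equal(a.params.W1, b_.params.W1)
        np.testing.assert_array_equal(a.params.W2, b_.params.W2)
        np.testing.assert_array_equal(a.params.b, b_.params.b)
        np.testing.assert_array_equal(a.loss_trace, b_.loss_trace)

    def test_recovers_true_variables_on_synthetic_data(self):
        """On a linear-hazard replicate the true variables carry the
        largest importances."""
        design = SimulationDesign(setting=1, scenario=1, p=10, N=200, up=3,
                                  corr="ar1", seed=42)
        rep = generate_replicate(design)
        fit = fit_cnt(rep.data, TGDRConfig(tau=0.9, K=200, h=5, seed=7))
        w12 = np.abs(importance(fit.params).w12)
        assert set(np.argsort(w12)[-3:]) == {0, 1, 2}

    def test_checkpoints_match_rerun(self, rng):
        data = random_survival_data(rng, n=30, p=5)
        long = fit_cnt(data, TGDRConfig(tau=0.8, K=50, h=3, seed=5),
                       checkpoints=(20,))
        short = fit_cnt(data, TGDRConfig(tau=0.8, K=20, h=3, seed=5))
        np.testing.assert_array_equal(
            long.checkpoints[20].W1, short.params.W1
        )

    def test_loss_trace_monotone_for_small_steps(self, rng):
        data = random_survival_data(rng, n=30, p=4)
        fit = fit_cnt(data, TGDRConfig(tau=0.0, K=60, h=3, seed=1,
                                       alpha0=1e-4))
        assert np.all(np.diff(fit.loss_trace) >= -1e-9)


class TestFitCt:
    def test_zero_iterations_leave_zero_coefficients(self, rng):
        data = random_survival_data(rng, n=20, p=4)
        fit = fit_ct(data, TGDRConfig(tau=0.5, K=0))
        np.testing.assert_array_equal(fit.params, np.zeros(4))

    def test_loss_trace_monotone_for_small_steps(self, rng):
        data = random_survival_data(rng, n=40, p=5)
        fit = fit_ct(data, TGDRConfig(tau=0.0, K=100, alpha0=0.005))
        assert np.all(np.diff(fit.loss_trace) >= -1e-9)

    def test_top_one_thresholding_bounds_support(self, rng):
        data = random_survival_data(rng, n=40, p=12)
        fit = fit_ct(data, TGDRConfig(tau=1.0, K=5))
        beta = fit.params
        assert np.count_nonzero(beta) <= 5
        assert np.all(beta[beta == 0.0] == 0.0)

    def test_single_covariate_recovers_unit_effect(self):
        """With p=1 the mask is always 1, so CT is plain gradient ascent;
        the estimate approaches the Cox MLE and the generating effect."""
        design = SimulationDesign(setting=1, scenario=1, p=1, N=500, up=1,
                                  corr="identity", seed=3)
        rep = generate_replicate(design)
        fit = fit_ct(rep.data, TGDRConfig(tau=0.0, K=400, alpha0=0.5, eta=1.0))
        beta_hat = fit.params[0]
        cph = CoxPHFitter().fit(
            rep.data.to_dataframe(), duration_col="time", event_col="status"
        )
        assert beta_hat == pytest.approx(cph.params_.iloc[0], abs=0.01)
        assert abs(beta_hat - 1.0) < 0.15

    def test_sparse_linear_truth_recovered_across_seeds(self):
        """Linear setting: CT selects nearly exactly the true support."""
        f1s = []
        for seed in range(20):
            design = SimulationDesign(setting=1, scenario=1, p=50, N=500,
                                      up=5, corr="ar1", seed=seed)
            rep = generate_replicate(design)
            fit = fit_ct(rep.data, TGDRConfig(tau=0.9, K=300))
            sel = importance(fit.params).selected
            tp = (sel & rep.truth).sum()
            fp = (sel & ~rep.truth).sum()
            fn = ((~sel) & rep.truth).sum()
            f1s.append(2 * tp / (2 * tp + fp + fn))
            assert tp == 5  # selected set contains the true set
        assert np.mean(f1s) > 0.8

    def test_bit_reproducible(self, rng):
        data = random_survival_data(rng, n=25, p=6)
        config = TGDRConfig(tau=0.8, K=30)
        np.testing.assert_array_equal(
            fit_ct(data, config).params, fit_ct(data, config).params
        )


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs", [{"tau": -0.1}, {"tau": 1.1}, {"K": -1}, {"alpha0": 0.0},
                   {"eta": 0.0}, {"h": 0}]
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TGDRConfig(**kwargs)
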