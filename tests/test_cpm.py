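import numpy as np
import pytest
from scipy import stats

import cpmkit as ck
from cpmkit.cpm import LoocvEngine


def brute_spearman(x, y):
    """Independent oracle: rank then Pearson."""
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


class TestPartialSpearman:
    def test_monotone_without_covariates(self):
        x = np.arange(10.0)
        y = x**3 + 2
        rho, p = ck.partial_spearman(x, y)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_reduces_to_plain_spearman(self, rng):
        for _ in range(200):
            x, y = rng.normal(size=(2, 12))
            rho, _ = ck.partial_spearman(x, y)
            assert rho == pytest.approx(brute_spearman(x, y), abs=1e-12)

    def test_pvalue_matches_scipy_convention(self, rng):
        x, y = rng.normal(size=(2, 15))
        rho, p = ck.partial_spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_covariate_absorbs_shared_signal(self, rng):
        # y IS the covariate: partialling it out must gut the correlation
        plain, partial = [], []
        for _ in range(300):
            cov = rng.normal(size=14)
            x = rng.normal(size=14)
            y = cov.copy()
            plain.append(abs(brute_spearman(x, y)))
            partial.append(abs(ck.partial_spearman(x, y, cov[:, None])[0]))
        assert np.median(partial) < np.median(plain)

    def test_constant_input_never_selected(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, p = ck.partial_spearman(np.ones(10), np.arange(10.0))
        assert (rho, p) == (0.0, 1.0)

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="observations"):
            ck.partial_spearman(np.arange(4.0), np.arange(4.0), np.ones((4, 2)))


class TestSelectEdges:
    def test_loose_threshold_selects_almost_everything(self, null_dataset):
        masks = ck.select_edges(null_dataset, 1 - 1e-9)
        frac = (masks.positive_mask | masks.negative_mask).mean()
        assert frac > 0.99

    def test_masks_disjoint_and_signed(self, null_dataset):
        masks = ck.select_edges(null_dataset, 0.2)
        assert not (masks.positive_mask & masks.negative_mask).any()
        q_rho = [
            ck.partial_spearman(
                null_dataset.edge_matrix[:, k],
                null_dataset.behaviour,
                null_dataset.covariates,
            )
            for k in np.flatnonzero(masks.positive_mask)[:5]
        ]
        assert all(r > 0 and p < 0.2 for r, p in q_rho)

    def test_null_type_one_rate_near_threshold(self):
        rates = []
        for s in range(50):
            d = ck.generate_null_cohort(12, 30, seed=2000 + s).to_dataset()
            m = ck.select_edges(d, 0.01)
            rates.append((m.positive_mask.sum() + m.negative_mask.sum()) / d.n_edges)
        assert 0.003 < np.mean(rates) < 0.03

    def test_planted_edges_recovered_noiseless(self):
        # strongly coherent planted network, no behavioural noise
        cohort = ck.generate_cohort(
            16, 30, 8, effect_scale=1.0, noise_sd=0.0, seed=77, latent_share=0.9
        )
        masks = ck.select_edges(cohort.to_dataset(), 0.05)
        assert set(cohort.truth.signal_edges) <= set(np.flatnonzero(masks.positive_mask))


class TestStrengthPrimitives:
    def test_network_strength_examples(self):
        assert ck.network_strength([0.3, -0.1, 0.5], [True, True, False]) == pytest.approx(0.2)
        assert ck.network_strength([0.3, -0.1], [False, False]) == 0.0
        with pytest.raises(ValueError):
            ck.network_strength([0.1], [True, False])

    def test_strength_additivity_over_disjoint_masks(self, rng):
        vals = rng.uniform(-1, 1, 50)
        a = rng.random(50) < 0.3
        b = ~a & (rng.random(50) < 0.3)
        assert ck.network_strength(vals, a | b) == pytest.approx(
            ck.network_strength(vals, a) + ck.network_strength(vals, b)
        )

    def test_fit_exact_line(self):
        s = np.array([0.0, 1.0, 2.0, 3.0])
        model = ck.fit_strength_model(s, 2 * s + 1)
        assert (model.slope, model.intercept) == (pytest.approx(2.0), pytest.approx(1.0))
        assert not model.degenerate

    def test_fit_matches_normal_equations(self, rng):
        s = rng.normal(size=30)
        y = rng.normal(size=30)
        model = ck.fit_strength_model(s, y)
        beta = np.linalg.solve(
            np.array([[30, s.sum()], [s.sum(), (s * s).sum()]]),
            np.array([y.sum(), (s * y).sum()]),
        )
        assert model.intercept == pytest.approx(beta[0], abs=1e-10)
        assert model.slope == pytest.approx(beta[1], abs=1e-10)

    def test_constant_strengths_degenerate_mean_fallback(self):
        model = ck.fit_strength_model(np.zeros(5), np.array([1.0, 2, 3, 4, 5]))
        assert model.degenerate
        assert model.predict(0.0) == pytest.approx(3.0)

    def test_uncorrelated_strength_slope_near_zero(self, rng):
        slopes = [
            ck.fit_strength_model(rng.normal(size=200), rng.normal(size=200)).slope
            for _ in range(100)
        ]
        assert abs(np.mean(slopes)) < 0.02


class TestLoocv:
    def test_fold_masks_disjoint(self, planted_cohort):
        fit = ck.loocv_predict(planted_cohort.to_dataset(), 0.05, 0.05)
        assert len(fit.fold_masks) == 20
        for m in fit.fold_masks:
            assert not (m.positive_mask & m.negative_mask).any()

    def test_no_leakage_from_left_out_subject(self, planted_cohort):
        data = planted_cohort.to_dataset()
        fit = ck.loocv_predict(data, 0.05, 0.05)
        for i in (0, 7, 19):
            y2 = data.behaviour.copy()
            y2[i] += 1000.0
            data2 = ck.CohortDataset(
                data.subject_ids, data.edge_matrix, y2, data.covariates
            )
            fit2 = ck.loocv_predict(data2, 0.05, 0.05)
            assert fit2.predicted_pos[i] == pytest.approx(fit.predicted_pos[i], abs=1e-12)
            assert fit2.predicted_neg[i] == pytest.approx(fit.predicted_neg[i], abs=1e-12)

    def test_scale_equivariance_of_selection_and_strengths(self, planted_cohort):
        data = planted_cohort.to_dataset()
        fit = ck.loocv_predict(data, 0.05, 0.05)
        scaled = ck.CohortDataset(
            data.subject_ids, data.edge_matrix * 0.5, data.behaviour, data.covariates
        )
        fit2 = ck.loocv_predict(scaled, 0.05, 0.05)
        for a, b in zip(fit.fold_masks, fit2.fold_masks):
            assert np.array_equal(a.positive_mask, b.positive_mask)
            assert np.array_equal(a.negative_mask, b.negative_mask)
        # rank-based accuracy is unchanged by a positive rescale of edges
        assert fit2.rho_pos == pytest.approx(fit.rho_pos, abs=1e-12)

    def test_planted_signal_predicts_well(self, planted_cohort):
        fit = ck.loocv_predict(planted_cohort.to_dataset(), 0.05, 0.05)
        assert fit.rho_pos > 0.4

    def test_null_cohorts_show_loocv_pessimism(self):
        rhos = []
        for s in range(60):
            d = ck.generate_null_cohort(12, 30, seed=3000 + s).to_dataset()
            fit = ck.loocv_predict(d, 0.05, 0.05)
            rhos += [fit.rho_pos, fit.rho_neg]
        assert np.mean(rhos) < 0.2

    def test_sweep_agrees_with_single_threshold_loocv(self, null_dataset):
        engine = LoocvEngine(null_dataset)
        thresholds = ck.ThresholdGrid(0.005, 0.05, 0.005).values
        sw = engine.sweep(null_dataset.behaviour, thresholds, thresholds)
        for k, thr in enumerate(thresholds):
            fit = engine.loocv(null_dataset.behaviour, thr, thr)
            assert np.allclose(sw["pred_pos"][:, k], fit.predicted_pos, atol=1e-10)
            assert np.allclose(sw["pred_neg"][:, k], fit.predicted_neg, atol=1e-10)
            assert sw["pos_curve"][k] == pytest.approx(fit.rho_pos, abs=1e-10)

    def test_threshold_bounds_validated(self, null_dataset):
        with pytest.raises(ValueError):
            ck.loocv_predict(null_dataset, 0.0, 0.05)
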