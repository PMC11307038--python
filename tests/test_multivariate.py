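"""PCA, imputation, centroid classification, outlier screen, loading ranks."""

import numpy as np
import pandas as pd
import pytest

from mirseparate import (
    apply_calibration,
    censor_and_filter,
    compute_calibration_factors,
    fit_pca,
    generate_cohort,
    loading_rank,
    mean_impute,
    pc_classify,
    pca_outlier_screen,
    simulate_raw_plates,
)
from mirseparate.datatypes import CtMatrix
from mirseparate.exceptions import ConfigError, DegenerateInputError
from mirseparate.metrics import confusion_counts, sensitivity_specificity

from conftest import make_cohort, make_ct_matrix


class TestMeanImpute:
    def test_arithmetic(self):
        m = make_ct_matrix([[20.0], [np.nan], [22.0]])
        out = mean_impute(m)
        assert out.values.iloc[1, 0] == pytest.approx(21.0)

    def test_complete_matrix_unchanged(self, rng):
        m = make_ct_matrix(rng.normal(30, 2, (4, 3)))
        pd.testing.assert_frame_equal(mean_impute(m).values, m.values)

    def test_feature_mean_conserved(self, rng):
        values = rng.normal(30, 2, (6, 4))
        values[2, 1] = np.nan
        values[4, 1] = np.nan
        m = make_ct_matrix(values)
        before = np.nanmean(values[:, 1])
        after = mean_impute(m).values.iloc[:, 1].mean()
        assert after == pytest.approx(before, abs=1e-12)

    def test_fully_missing_feature_rejected(self):
        m = make_ct_matrix([[1.0, np.nan], [2.0, np.nan]])
        with pytest.raises(DegenerateInputError):
            mean_impute(m)


class TestFitPca:
    def test_two_samples_pc1_explains_everything(self, rng):
        m = make_ct_matrix(rng.normal(30, 2, (2, 5)))
        model = fit_pca(m)
        assert model.variance_ratio[0] == pytest.approx(1.0)

    def test_variance_fractions_conserved_at_full_rank(self, rng):
        m = make_ct_matrix(rng.normal(30, 2, (8, 5)))
        model = fit_pca(m)
        assert model.variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)
        assert all(np.diff(model.variance_ratio) <= 1e-12)

    def test_matches_covariance_eigendecomposition(self, rng):
        """Independent oracle: eigendecompose the sample covariance matrix."""
        X = rng.normal(0, 1, (8, 5))
        model = fit_pca(make_ct_matrix(X))
        cov = np.cov(X, rowvar=False, ddof=1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        explained = evals / evals.sum()
        assert np.allclose(model.variance_ratio, explained[: model.n_components], atol=1e-8)
        for j in range(model.n_components):
            got = model.loadings.iloc[:, j].to_numpy()
            want = evecs[:, j]
            assert np.allclose(np.abs(got), np.abs(want), atol=1e-8)

    def test_loadings_orthonormal_and_reconstruction(self, rng):
        X = rng.normal(0, 1, (7, 4))
        m = make_ct_matrix(X)
        model = fit_pca(m)
        L = model.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-9)
        centered = X - X.mean(axis=0)
        assert np.allclose(model.scores.to_numpy() @ L.T, centered, atol=1e-8)
        assert np.allclose(
            (pd.DataFrame(centered, index=m.values.index, columns=m.values.columns)
             @ model.loadings).to_numpy(),
            model.scores.to_numpy(),
            atol=1e-8,
        )

    def test_sign_convention_is_deterministic(self, rng):
        X = rng.normal(0, 1, (6, 4))
        a = fit_pca(make_ct_matrix(X))
        b = fit_pca(make_ct_matrix(-X))
        for j in range(a.n_components):
            col_a = a.loadings.iloc[:, j]
            assert col_a.iloc[np.argmax(np.abs(col_a.to_numpy()))] > 0
            col_b = b.loadings.iloc[:, j]
            assert col_b.iloc[np.argmax(np.abs(col_b.to_numpy()))] > 0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_pca(make_ct_matrix(np.full((4, 3), 30.0)))
        with pytest.raises(ConfigError):
            fit_pca(make_ct_matrix([[1.0, np.nan], [2.0, 3.0]]))


def clustered_matrix(rng, n_per_group=6, separation=10.0, spread=0.5, p=4):
    cohort = make_cohort(
        {
            "LRRK2_MC": [f"L{i}" for i in range(n_per_group)],
            "sPD": [f"P{i}" for i in range(n_per_group)],
        }
    )
    a = rng.normal(0, spread, (n_per_group, p))
    b = rng.normal(0, spread, (n_per_group, p)) + separation
    return make_ct_matrix(np.vstack([a, b]), sample_ids=cohort.sample_ids), cohort


class TestPcClassify:
    def test_separated_clouds_perfect(self, rng):
        m, cohort = clustered_matrix(rng)
        model = fit_pca(m)
        for dims in (1, 2):
            cls = pc_classify(model, cohort, dims=dims)
            assert cls.sensitivity == 1.0
            assert cls.specificity == 1.0

    def test_single_sample_per_group_trivially_correct(self, rng):
        cohort = make_cohort({"LRRK2_MC": ["L0"], "sPD": ["P0"]})
        m = make_ct_matrix(rng.normal(0, 1, (2, 3)), sample_ids=cohort.sample_ids)
        cls = pc_classify(fit_pca(m), cohort, dims=1)
        assert cls.sensitivity == 1.0 and cls.specificity == 1.0

    def test_metrics_match_brute_force_confusion(self, rng):
        m, cohort = clustered_matrix(rng, separation=1.0, spread=1.0)
        model = fit_pca(m)
        cls = pc_classify(model, cohort, dims=2)
        truth = cohort.groups_of(cls.predicted.index)
        tp, fn, tn, fp = confusion_counts(truth.to_numpy(), cls.predicted.to_numpy())
        sens, spec = sensitivity_specificity(tp, fn, tn, fp)
        assert cls.sensitivity == pytest.approx(sens)
        assert cls.specificity == pytest.approx(spec)
        assert cls.confusion == (tp, fn, tn, fp)

    def test_shuffled_labels_chance_level(self):
        """Permuted labels: sensitivity + specificity centered at one."""
        rng = np.random.default_rng(12)
        totals = []
        for _ in range(40):
            n = 10
            cohort = make_cohort(
                {"LRRK2_MC": [f"L{i}" for i in range(n)], "sPD": [f"P{i}" for i in range(n)]}
            )
            X = rng.normal(0, 1, (2 * n, 5))  # no group structure at all
            m = make_ct_matrix(X, sample_ids=cohort.sample_ids)
            cls = pc_classify(fit_pca(m), cohort, dims=1)
            totals.append(cls.sensitivity + cls.specificity)
        # 95% empirical band of the null distribution must cover chance (= 1)
        lo, hi = np.quantile(totals, [0.025, 0.975])
        assert lo <= 1.0 <= hi


class TestOutlierScreen:
    def test_planted_global_shift_is_flagged(self, small_config):
        sid = "sPD-02"
        cfg = small_config.with_(outlier_sample=(sid, 6.0))
        cohort = generate_cohort(cfg)
        plates, _ = simulate_raw_plates(cohort, cfg)
        mats = apply_calibration(plates, compute_calibration_factors(plates))
        filtered, _ = censor_and_filter(mats["plasma"], cohort)
        model = fit_pca(mean_impute(filtered), n_components=2)
        assert sid in pca_outlier_screen(model, k_sd=3.0)

    def test_homogeneous_cloud_rarely_flags(self):
        rng = np.random.default_rng(4)
        flags = 0
        n_sims, n = 40, 200
        for _ in range(n_sims):
            m = make_ct_matrix(rng.normal(30, 1, (n, 6)))
            flags += len(pca_outlier_screen(fit_pca(m, n_components=2), k_sd=3.0))
        # Gaussian rate beyond 3 robust SDs on two components is ~0.5%;
        # at this n the MAD scale estimate is stable enough to stay below 1%
        assert flags / (n_sims * n) < 0.01

    def test_k_zero_flags_everything_off_median(self, rng):
        m = make_ct_matrix(rng.normal(30, 1, (9, 4)))
        model = fit_pca(m, n_components=2)
        flagged = pca_outlier_screen(model, k_sd=0.0)
        off_median = {
            s
            for col in ("PC1", "PC2")
            for s in model.scores.index[model.scores[col] != model.scores[col].median()]
        }
        assert set(flagged) == off_median

    def test_needs_three_samples(self, rng):
        m = make_ct_matrix(rng.normal(0, 1, (2, 3)))
        with pytest.raises(ConfigError):
            pca_outlier_screen(fit_pca(m))


class TestLoadingRank:
    def test_planted_variance_feature_ranks_first(self, rng):
        X = rng.normal(0, 0.05, (12, 6))
        X[:6, 3] += 5.0  # feature 4 carries all the between-sample variance
        model = fit_pca(make_ct_matrix(X))
        ranked = loading_rank(model, component=1, k=3)
        assert ranked[0] == "miR-t04"

    def test_k_equals_n_returns_all(self, rng):
        model = fit_pca(make_ct_matrix(rng.normal(0, 1, (5, 4))))
        assert len(loading_rank(model, k=4)) == 4
        assert len(loading_rank(model, k=99)) == 4

    def test_invariant_to_component_sign_flip(self, rng):
        X = rng.normal(0, 1, (6, 5))
        model = fit_pca(make_ct_matrix(X))
        flipped = model.loadings.copy()
        flipped["PC1"] = -flipped["PC1"]
        from mirseparate.multivariate import PcaModel

        other = PcaModel(
            feature_means=model.feature_means,
            loadings=flipped,
            scores=model.scores,
            variance_ratio=model.variance_ratio,
        )
        assert loading_rank(model) == loading_rank(other)
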