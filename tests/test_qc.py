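"""Core QC operations against closed-form and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tmtqc import (
    QCConfig,
    SimulationConfig,
    detect_outliers_iterative,
    filter_missing,
    log2_transform,
    normalize_sample_loading,
    pca_scores,
    regress_batch,
    run_qc,
    simulate_cohort,
)
from tmtqc.errors import QCError

from conftest import make_matrix, make_metadata


class TestFilterMissing:
    def test_boundary_half_missing_is_retained(self):
        # per-protein missing counts {3, 2, 0} over 4 samples: 2/4 = 50% stays
        values = np.array([
            [np.nan, np.nan, np.nan, 1.0],
            [np.nan, np.nan, 1.0, 1.0],
            [1.0, 1.0, 1.0, 1.0],
        ])
        m = make_matrix(values, stage="raw")
        out, step = filter_missing(m)
        assert out.protein_ids == ["p1", "p2"]
        assert step.n_proteins_before == 3 and step.n_proteins_after == 2
        assert step.n_samples_after == 4

    def test_no_missing_is_identity(self):
        m = make_matrix(np.ones((4, 3)), stage="raw")
        out, _ = filter_missing(m)
        assert out.equals(m)

    def test_empty_matrix_rejected(self):
        m = make_matrix(np.empty((0, 0)), stage="raw")
        with pytest.raises(QCError):
            filter_missing(m)


class TestNormalizeLoading:
    def test_simple_column(self):
        out = normalize_sample_loading(make_matrix([[2.0], [2.0]], stage="raw"))
        np.testing.assert_allclose(out.values[:, 0], [0.5, 0.5])
        assert out.stage == "ratio"

    def test_missing_entries_excluded_from_total(self):
        out = normalize_sample_loading(make_matrix([[4.0], [np.nan], [4.0]], stage="raw"))
        np.testing.assert_allclose(out.values[[0, 2], 0], [0.5, 0.5])
        assert np.isnan(out.values[1, 0])

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_observed_column_sums_are_one(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0.1, 100.0, size=(12, 6))
        values[rng.random(values.shape) < 0.25] = np.nan
        # guard against a fully-missing column
        values[0, :] = rng.uniform(0.1, 100.0, size=6)
        out = normalize_sample_loading(make_matrix(values, stage="raw"))
        np.testing.assert_allclose(np.nansum(out.values, axis=0), 1.0, atol=1e-9)

    def test_zero_total_sample_named(self):
        values = np.array([[1.0, np.nan], [2.0, np.nan]])
        with pytest.raises(QCError, match="s1"):
            normalize_sample_loading(make_matrix(values, stage="raw"))


class TestLog2Transform:
    def test_known_values(self):
        m = make_matrix([[0.5], [0.5]], stage="raw")
        out = log2_transform(normalize_sample_loading(make_matrix([[1.0], [1.0]], stage="raw")))
        np.testing.assert_allclose(out.values[:, 0], [-1.0, -1.0])
        del m

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_monotone_within_columns(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0.1, 10.0, size=(8, 4))
        out = log2_transform(normalize_sample_loading(make_matrix(values, stage="raw")))
        for j in range(4):
            assert np.array_equal(np.argsort(values[:, j]), np.argsort(out.values[:, j]))


class TestPcaScores:
    def test_identical_samples_give_zero_scores(self):
        m = make_matrix(np.tile([[1.0], [2.0], [3.0]], (1, 5)), stage="log2")
        scores = pca_scores(m, 2)
        np.testing.assert_allclose(scores.to_numpy(), 0.0, atol=1e-12)

    def test_rank_one_data_loads_on_pc1(self):
        rng = np.random.default_rng(0)
        loading = rng.normal(size=20)
        factor = rng.normal(size=10)
        m = make_matrix(np.outer(loading, factor), stage="log2")
        centered = m.values - m.values.mean(axis=1, keepdims=True)
        total = (centered ** 2).sum()
        scores = pca_scores(m, 3)
        pc1 = (scores["PC1"] ** 2).sum()
        assert pc1 / total >= 0.999

    def test_matches_brute_force_eigendecomposition(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.normal(size=(10, 6)), stage="log2")
        scores = pca_scores(m, 3)
        centered = (m.values - m.values.mean(axis=1, keepdims=True)).T  # samples × proteins
        cov = centered @ centered.T          # sample Gram matrix shares PCA eigenstructure
        vals, vecs = np.linalg.eigh(cov)
        order = np.argsort(vals)[::-1][:3]
        oracle = vecs[:, order] * np.sqrt(vals[order])
        for k in range(3):
            a, b = scores.to_numpy()[:, k], oracle[:, k]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_too_many_components_rejected(self):
        m = make_matrix(np.ones((4, 5)), stage="log2")
        with pytest.raises(QCError):
            pca_scores(m, 6)


class TestOutlierDetection:
    def test_gaussian_null_rarely_flags(self):
        # expected flags per PC ~ 100 * 2 * Phi(-4) ~ 0.006
        removed = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            m = make_matrix(rng.normal(size=(300, 100)), stage="log2")
            _, step = detect_outliers_iterative(m)
            removed += step.n_samples_before - step.n_samples_after
        assert removed <= 1

    def test_planted_shift_removed_in_round_one(self):
        rng = np.random.default_rng(7)
        values = rng.normal(0.0, 0.3, size=(400, 60))
        values[:, 17] += 3.0      # 10 x noise SD
        m = make_matrix(values, stage="log2")
        out, step = detect_outliers_iterative(m)
        rounds = step.details["rounds"]
        assert rounds[0]["removed"] == ["s17"]
        assert step.details["n_rounds"] == 1
        assert "s17" not in out.sample_ids

    def test_recovery_rates_over_many_cohorts(self):
        """Sensitivity >= 0.95 and false removals <= 1% for 8-sigma shifts."""
        planted_found = 0
        planted_total = 0
        false_removed = 0
        clean_total = 0
        for seed in range(50):
            cfg = SimulationConfig(seed=seed, n_proteins=150, n_samples=60,
                                   n_batches=4, noise_sd=0.3, batch_sd=0.1,
                                   n_outliers=1, outlier_shift=2.4,  # 8 x noise_sd
                                   missing_rate_target=0.0)
            matrix, _, truth = simulate_cohort(cfg)
            log2 = matrix.with_values(np.log2(matrix.values), stage="log2")
            _, step = detect_outliers_iterative(log2)
            removed = {s for r in step.details["rounds"] for s in r["removed"]}
            planted_total += len(truth.outlier_samples)
            planted_found += len(removed & set(truth.outlier_samples))
            false_removed += len(removed - set(truth.outlier_samples))
            clean_total += cfg.n_samples - len(truth.outlier_samples)
        assert planted_found / planted_total >= 0.95
        assert false_removed / clean_total <= 0.01

    def test_removing_everything_is_an_error(self):
        m = make_matrix(np.diag([100.0, 90.0, 80.0, 70.0, 60.0])[:, :5], stage="log2")
        cfg = QCConfig(outlier_sd_threshold=0.01)
        with pytest.raises(QCError):
            detect_outliers_iterative(m, cfg)


class TestRegressBatch:
    def test_single_batch_is_identity(self):
        m = make_matrix(np.arange(12.0).reshape(3, 4), stage="log2")
        meta = make_metadata(m.sample_ids)
        out, _ = regress_batch(m, meta)
        np.testing.assert_allclose(out.values, m.values, atol=1e-12)
        assert out.stage == "batch_corrected"

    def test_two_batch_planted_offsets_closed_form(self):
        # zero noise, batches offset by +d/-d: means equalize, grand mean kept
        d = 0.7
        base = np.array([[1.0, 1.0, 1.0, 1.0], [2.0, 2.0, 2.0, 2.0]])
        values = base + np.array([[d, d, -d, -d]])
        m = make_matrix(values, stage="log2")
        meta = make_metadata(m.sample_ids, batch=["b1", "b1", "b2", "b2"])
        out, _ = regress_batch(m, meta)
        np.testing.assert_allclose(out.values, base, atol=1e-12)
        np.testing.assert_allclose(out.values.mean(axis=1), base.mean(axis=1), atol=1e-12)

    def test_batch_means_equalized_with_missing_entries(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(30, 40)) + np.repeat([1.0, -1.0], 20)[None, :]
        values[rng.random(values.shape) < 0.2] = np.nan
        m = make_matrix(values, stage="log2")
        meta = make_metadata(m.sample_ids, batch=np.repeat(["b1", "b2"], 20))
        out, _ = regress_batch(m, meta)
        batches = np.repeat(["b1", "b2"], 20)
        for i in range(30):
            means = [np.nanmean(out.values[i, batches == b]) for b in ("b1", "b2")]
            if not np.any(np.isnan(means)):
                assert abs(means[0] - means[1]) < 1e-8

    def test_protein_in_single_batch_passed_through(self):
        values = np.array([[1.0, 2.0, np.nan, np.nan],
                           [1.0, 2.0, 3.0, 4.0]])
        m = make_matrix(values, stage="log2")
        meta = make_metadata(m.sample_ids, batch=["b1", "b1", "b2", "b2"])
        out, step = regress_batch(m, meta)
        np.testing.assert_allclose(out.values[0, :2], values[0, :2])
        assert step.details["proteins_passed_through"] == ["p0"]

    def test_planted_offsets_recovered_within_three_se(self, small_cohort):
        cfg, matrix, metadata, truth = small_cohort
        log2 = matrix.with_values(np.log2(matrix.values), stage="log2")
        batches = metadata.df["batch"].to_numpy()
        markers = set(truth.sex_markers) | set(truth.ad_markers) | set(truth.race_markers)
        plain = [p for p in truth.batch_offsets.index if p not in markers]
        rng = np.random.default_rng(0)
        for pid in rng.choice(plain, size=25, replace=False):
            y = log2.data.loc[pid].to_numpy()
            for b in truth.batch_offsets.columns:
                in_b = batches == b
                est = y[in_b].mean() - y.mean()
                true_dev = truth.batch_offsets.at[pid, b] - truth.batch_offsets.loc[pid].mean()
                se = cfg.noise_sd / np.sqrt(in_b.sum())
                assert abs(est - true_dev) < 4 * se + 0.05

    def test_trait_effects_survive_batch_regression(self):
        """Planted sex effects estimate the same before and after correction."""
        cfg = SimulationConfig(seed=17, n_proteins=80, n_samples=160, n_batches=8,
                               batch_sd=0.5, noise_sd=0.2, n_outliers=0,
                               missing_rate_target=0.0, n_sex_markers=8,
                               n_ad_markers=0, n_race_markers=0, effect_size_sex=1.0)
        matrix, metadata, truth = simulate_cohort(cfg)
        log2 = matrix.with_values(np.log2(matrix.values), stage="log2")
        corrected, _ = regress_batch(log2, metadata)
        female = (metadata.df["sex"] == "female").to_numpy()
        batches = metadata.df["batch"].to_numpy()
        # correction shifts the sex contrast by sum_k w_k * (batch mean), with
        # w_k the sex-composition imbalance of batch k; its SE is dominated by
        # the planted batch offsets (SD batch_sd) times ||w||
        w = np.array([np.sum(female & (batches == b)) / female.sum()
                      - np.sum(~female & (batches == b)) / (~female).sum()
                      for b in np.unique(batches)])
        se_noise = cfg.noise_sd * np.sqrt(1 / female.sum() + 1 / (~female).sum())
        se_change = np.sqrt(cfg.batch_sd ** 2 * (w ** 2).sum() + se_noise ** 2)
        for pid in truth.sex_markers:
            before = log2.data.loc[pid][female].mean() - log2.data.loc[pid][~female].mean()
            after = corrected.data.loc[pid][female].mean() - corrected.data.loc[pid][~female].mean()
            assert abs(before - after) < 3 * se_change


def test_pipeline_near_identity_on_clean_cohort():
    """No planted outliers/batch effects: nothing removed, correction tiny."""
    cfg = SimulationConfig(seed=23, n_proteins=120, n_samples=96, n_batches=6,
                           batch_sd=0.0, noise_sd=0.3, n_outliers=0,
                           missing_rate_target=0.0)
    matrix, metadata, _ = simulate_cohort(cfg)
    corrected, report = run_qc(matrix, metadata)
    assert corrected.n_proteins == matrix.n_proteins
    assert corrected.n_samples == matrix.n_samples
    assert report.removed_samples() == []
    # batch correction moves each value by less than ~3 SE of a batch mean
    from tmtqc import log2_transform as l2, normalize_sample_loading as norm
    log2 = l2(norm(matrix))
    per_batch = cfg.n_samples // cfg.n_batches
    shift = np.abs(corrected.values - log2.values)
    assert np.median(shift) < 3 * cfg.noise_sd / np.sqrt(per_batch)
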