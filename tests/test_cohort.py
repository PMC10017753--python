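"""Synthetic cohort generator: contracts, determinism, planted effects, and
the cohort-table statistics."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from connsae.cohort import (CohortConfig, MotionSummary, apply_motion_exclusion,
                            chi_square_independence, generate_cohort,
                            generate_functional_correlations,
                            generate_structural_counts,
                            make_functional_profile, make_structural_profile,
                            welch_t_from_summary)
from connsae.networks import build_structural_network


def cohen_d(a: np.ndarray, b: np.ndarray) -> float:
    sp = np.sqrt(((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
                 / (len(a) + len(b) - 2))
    return float((a.mean() - b.mean()) / sp)


def nodal_strengths(counts: np.ndarray) -> np.ndarray:
    return build_structural_network(counts).weights.sum(axis=1)


class TestCohortContracts:
    def test_group_sizes(self, null_cohort):
        labels = null_cohort.labels
        assert len(labels) == 20 and labels.sum() == 10

    def test_structural_matrix_contract(self, null_cohort):
        for counts in null_cohort.structural_counts:
            assert counts.shape == (78, 78)
            assert np.array_equal(counts, counts.T)
            assert np.all(counts >= 0)
            assert np.all(np.diag(counts) == 0)
            assert np.array_equal(counts, np.round(counts))  # integer counts

    def test_functional_matrix_contract(self, null_cohort):
        for corr in null_cohort.functional_corr:
            assert corr.shape == (59, 59)
            assert np.allclose(corr, corr.T)
            assert np.allclose(np.diag(corr), 1.0)
            assert np.all(np.abs(corr) <= 1 + 1e-12)
            assert np.linalg.eigvalsh(corr).min() >= -1e-8  # PSD by construction

    def test_subject_fields(self, null_cohort):
        for s in null_cohort.subjects:
            assert s.group in ("tbi", "control")
            assert s.handedness == "right"
            assert 30 <= s.inattention_t <= 100
            assert 30 <= s.hyperactivity_t <= 100

    def test_determinism_same_seed(self):
        cfg = CohortConfig(n_per_group=3, seed=11)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        assert a.metadata_frame().equals(b.metadata_frame())
        for ma, mb in zip(a.structural_counts, b.structural_counts):
            assert np.array_equal(ma, mb)
        for ma, mb in zip(a.functional_corr, b.functional_corr):
            assert np.array_equal(ma, mb)

    def test_different_seed_differs(self):
        a = generate_cohort(CohortConfig(n_per_group=3, seed=1))
        b = generate_cohort(CohortConfig(n_per_group=3, seed=2))
        assert not np.array_equal(a.structural_counts[0], b.structural_counts[0])

    def test_save_load_roundtrip(self, tmp_path, planted_cohort):
        planted_cohort.save(tmp_path)
        loaded = type(planted_cohort).load(tmp_path)
        assert len(loaded.subjects) == len(planted_cohort.subjects)
        assert np.array_equal(loaded.structural_counts[0],
                              planted_cohort.structural_counts[0])
        assert np.allclose(loaded.functional_corr[-1],
                           planted_cohort.functional_corr[-1], atol=1e-9)
        assert loaded.ground_truth["effect_size"] == 2.0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CohortConfig(n_per_group=1)
        with pytest.raises(ValueError):
            CohortConfig(effect_size=-1)
        with pytest.raises(ValueError):
            CohortConfig(effect_nodes=[("struct", 78)])
        with pytest.raises(ValueError):
            CohortConfig(effect_nodes=[("weird", 0)])
        with pytest.raises(ValueError):
            CohortConfig(symptom_coupling=[("struct_strength_0", "mood", 1.0)])
        with pytest.raises(ValueError):
            CohortConfig(symptom_coupling=[("bogus", "inattention_t", 1.0)])


class TestGenerators:
    def test_density_one_gives_complete_support(self):
        cfg = CohortConfig(n_per_group=2, struct_density=1.0, seed=0)
        profile = make_structural_profile(cfg, np.random.default_rng(0))
        counts = generate_structural_counts(profile, cfg, 0)
        off = ~np.eye(78, dtype=bool)
        assert np.all(counts[off] > 0)

    def test_noise_only_correlations_centred(self):
        cfg = CohortConfig(n_per_group=2, loading_module=0.0,
                           loading_global=0.0, seed=0)
        profile = make_functional_profile(cfg, np.random.default_rng(0))
        rng = np.random.default_rng(1)
        means = [generate_functional_correlations(profile, cfg, rng)
                 [np.triu_indices(59, 1)].mean() for _ in range(100)]
        assert abs(np.mean(means)) < 0.005

    def test_shared_factor_drives_correlation_to_one(self):
        cfg = CohortConfig(n_per_group=2, n_func_nodes=2, n_modules=1,
                           loading_module=1.0, loading_global=0.0,
                           ts_noise_sd=1e-6, ts_length=200, seed=0)
        profile = make_functional_profile(cfg, np.random.default_rng(0))
        corr = generate_functional_correlations(profile, cfg, 5)
        assert corr[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_planted_structural_effect_size_recovered(self):
        """d=2 planted on one node yields |d_hat| in [1, 3] on nodal strength."""
        dhats = []
        for seed in range(50):
            cfg = CohortConfig(n_per_group=20, effect_nodes=[("struct", 5)],
                               effect_size=2.0, seed=seed)
            coh = generate_cohort(cfg)
            y = coh.labels
            vals = np.array([nodal_strengths(m)[5] for m in coh.structural_counts])
            dhats.append(cohen_d(vals[y == 0], vals[y == 1]))
        assert 1.0 <= np.mean(dhats) <= 3.0

    def test_planted_effect_detected_at_study_size(self):
        """d=1.5 at n=55/group detected (Welch p<0.05) in >=80% of cohorts."""
        hits = 0
        n_sim = 50
        for seed in range(n_sim):
            cfg = CohortConfig(n_per_group=55, effect_nodes=[("struct", 7)],
                               effect_size=1.5, seed=seed)
            coh = generate_cohort(cfg)
            y = coh.labels
            vals = np.array([nodal_strengths(m)[7] for m in coh.structural_counts])
            _, p = stats.ttest_ind(vals[y == 0], vals[y == 1], equal_var=False)
            hits += p < 0.05
        assert hits >= 0.8 * n_sim

    def test_null_calibration_on_nodal_strength(self):
        """No planted effects: group-difference rejections occur at ~alpha."""
        fractions = []
        for seed in range(120):
            coh = generate_cohort(CohortConfig(n_per_group=10, seed=1000 + seed))
            y = coh.labels
            S = np.array([nodal_strengths(m) for m in coh.structural_counts])
            _, p = stats.ttest_ind(S[y == 0], S[y == 1], axis=0, equal_var=False)
            fractions.append((p < 0.05).mean())
        mean_frac = np.mean(fractions)
        se = np.std(fractions, ddof=1) / np.sqrt(len(fractions))
        assert abs(mean_frac - 0.05) <= 2 * se + 0.01

    def test_symptom_coupling_induces_correlation(self):
        cfg = CohortConfig(n_per_group=30, seed=19,
                           symptom_coupling=[("struct_strength_3",
                                              "inattention_t", 8.0)])
        coh = generate_cohort(cfg)
        vals = np.array([nodal_strengths(m)[3] for m in coh.structural_counts])
        t = np.array([s.inattention_t for s in coh.subjects])
        y = coh.labels
        # within controls the coupling is unconfounded by the group contrast
        r, p = stats.pearsonr(vals[y == 0], t[y == 0])
        assert r > 0 and p < 0.05


class TestMotionExclusion:
    def test_exceeding_translation_excludes(self):
        assert not apply_motion_exclusion(MotionSummary(2.5, 0.0, 0.0))

    def test_zero_motion_included(self):
        assert apply_motion_exclusion(MotionSummary(0.0, 0.0, 0.0))

    def test_boundary_values_included(self):
        assert apply_motion_exclusion(MotionSummary(2.0, 5.0, 0.2))

    def test_negative_motion_rejected(self):
        with pytest.raises(ValueError):
            MotionSummary(-0.1, 0.0, 0.0)


class TestGroupStatistics:
    def test_chi_square_matched_cohort_values(self):
        stat, df, p = chi_square_independence([[30, 25], [33, 22]])
        assert stat == pytest.approx(0.334, abs=5e-4)
        assert df == 1
        stat, df, _ = chi_square_independence([[30, 8, 17], [36, 11, 8]])
        assert stat == pytest.approx(4.259, abs=5e-4)
        assert df == 2

    def test_chi_square_independent_table_is_zero(self):
        stat, _, p = chi_square_independence([[10, 10], [10, 10]])
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_chi_square_matches_expected_count_bruteforce(self, rng):
        """Pearson statistic equals the direct expected-count formula on a
        grid of small 2x2 and 2x3 tables."""
        for _ in range(60):
            shape = (2, int(rng.integers(2, 4)))
            tab = rng.integers(1, 51, size=shape).astype(float)
            stat, df, _ = chi_square_independence(tab)
            total = tab.sum()
            expected = np.outer(tab.sum(1), tab.sum(0)) / total
            assert stat == pytest.approx(((tab - expected) ** 2 / expected).sum())
            assert df == (shape[0] - 1) * (shape[1] - 1)

    def test_chi_square_input_validation(self):
        with pytest.raises(ValueError):
            chi_square_independence([[1, 2]])
        with pytest.raises(ValueError):
            chi_square_independence([[0, 0], [1, 2]])
        with pytest.raises(ValueError):
            chi_square_independence([[-1, 2], [1, 2]])

    def test_welch_identical_groups_zero(self):
        t, _, p = welch_t_from_summary(10, 2, 30, 10, 2, 30)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_welch_antisymmetric(self):
        t1, df1, p1 = welch_t_from_summary(46.15, 6.02, 55, 64.73, 13.49, 55)
        t2, df2, p2 = welch_t_from_summary(64.73, 13.49, 55, 46.15, 6.02, 55)
        assert t1 == pytest.approx(-t2) and df1 == pytest.approx(df2)
        assert p1 == pytest.approx(p2)

    def test_welch_inattention_summaries(self):
        t, _, p = welch_t_from_summary(46.15, 6.02, 55, 64.73, 13.49, 55)
        assert t == pytest.approx(-9.33, abs=0.01)
        assert p < 1e-10

    def test_welch_input_validation(self):
        with pytest.raises(ValueError):
            welch_t_from_summary(1, 1, 1, 2, 1, 30)
        with pytest.raises(ValueError):
            welch_t_from_summary(1, 0, 30, 2, 1, 30)
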