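import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lsrcnv import evaluation as ev
from lsrcnv.evaluation import (
    build_contrast,
    contrast_label,
    fit_lda,
    geometric_mean_p,
    retained_split_indices,
    roc_auc,
    roc_pvalue,
    run_split,
    trimmed_cv,
)


def pair_count_auc(scores, labels):
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1 for a in pos for b in neg if a > b)
    ties = sum(1 for a in pos for b in neg if a == b)
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_ranking(self):
        _, auc = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert auc == 1.0

    def test_all_tied_scores(self):
        _, auc = roc_auc([5, 5, 5, 5], [0, 1, 0, 1])
        assert auc == 0.5

    def test_hand_set_with_tie_matches_pair_counting(self):
        scores = [0.1, 0.4, 0.4, 0.8, 0.4, 0.9]
        labels = [0, 0, 1, 1, 0, 1]
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(pair_count_auc(scores, labels))

    def test_random_sets_match_pair_counting(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 30))
            scores = np.round(rng.random(n), 1)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] ^= 1
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(pair_count_auc(scores, labels))

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        labels[0], labels[1] = 0, 1
        _, auc = roc_auc(scores, labels)
        _, auc2 = roc_auc(np.exp(3 * scores), labels)
        assert auc == pytest.approx(auc2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [1, 1])


def exact_permutation_p(scores, labels):
    """Enumerate all label assignments; p = fraction with AUC >= observed."""
    n_pos = sum(labels)
    obs = pair_count_auc(scores, labels)
    count = total = 0
    for combo in itertools.combinations(range(len(scores)), n_pos):
        perm = [1 if i in combo else 0 for i in range(len(scores))]
        total += 1
        if pair_count_auc(scores, perm) >= obs - 1e-12:
            count += 1
    return count / total


class TestRocPvalue:
    def test_chance_level_scores(self):
        p = roc_pvalue([5, 5, 5, 5, 5, 5], [0, 1, 0, 1, 0, 1])
        assert p >= 0.45

    def test_strong_separation_large_n(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 200), rng.normal(3, 1, 200)])
        labels = np.r_[np.zeros(200, int), np.ones(200, int)]
        assert roc_pvalue(scores, labels) < 1e-6

    def test_normal_approximation_close_to_exact_enumeration(self, rng):
        for _ in range(5):
            n_pos, n_neg = 5, 6
            scores = np.round(
                np.concatenate([rng.normal(0.6, 0.5, n_pos), rng.normal(0, 0.5, n_neg)]), 1
            )
            labels = np.r_[np.ones(n_pos, int), np.zeros(n_neg, int)]
            p_norm = roc_pvalue(scores, labels, method="normal")
            p_exact = roc_pvalue(scores, labels, method="exact")
            p_enum = exact_permutation_p(list(scores), list(labels))
            assert p_exact == pytest.approx(p_enum, abs=1e-9)
            assert abs(p_norm - p_exact) < 0.02


class TestGeometricMeanP:
    @pytest.mark.parametrize(
        "ps,expected",
        [([0.01, 0.01], 0.01), ([1, 1, 1], 1.0), ([0.1, 0.001], 0.01)],
    )
    def test_values(self, ps, expected):
        assert geometric_mean_p(ps) == pytest.approx(expected)

    def test_zero_rejected(self):
        with pytest.raises(ValueError):
            geometric_mean_p([0.1, 0.0])


class TestLDA:
    def test_isotropic_clouds_recover_mean_difference_direction(self, rng):
        mu = np.array([1.5, -0.5, 0.8])
        X_pos = rng.normal(0, 1, (4000, 3)) + mu
        X_neg = rng.normal(0, 1, (4000, 3))
        X = np.vstack([X_pos, X_neg])
        y = np.r_[np.ones(4000, int), np.zeros(4000, int)]
        scorer = fit_lda(X, y)
        w = scorer.weights / np.linalg.norm(scorer.weights)
        d = mu / np.linalg.norm(mu)
        assert np.allclose(w, d, atol=0.05)

    def test_duplicated_column_ridge_keeps_ranking(self, rng):
        x = rng.normal(size=40)
        y = (x + rng.normal(0, 0.5, 40) > 0).astype(int)
        single = fit_lda(x[:, None], y).score(x[:, None])
        dup = fit_lda(np.c_[x, x], y).score(np.c_[x, x])
        assert np.all(np.isfinite(dup))
        assert stats.spearmanr(single, dup).statistic == pytest.approx(1.0)

    def test_one_feature_is_monotone_in_raw_feature(self, rng):
        x = rng.normal(size=30)
        y = (x > 0).astype(int)
        scores = fit_lda(x[:, None], y).score(x[:, None])
        assert stats.spearmanr(scores, x).statistic == pytest.approx(1.0)

    def test_matches_sklearn_ranking(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X = rng.normal(size=(60, 3)) @ rng.normal(size=(3, 3))
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        ours = fit_lda(X, y).score(X)
        ref = LinearDiscriminantAnalysis().fit(X, y).decision_function(X)
        assert stats.spearmanr(ours, ref).statistic == pytest.approx(1.0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_lda(np.zeros((3, 2)), [1, 0, 0])


class TestContrasts:
    def test_class_nesting(self, cohort):
        """lethal positives are fast-recurrent; fast positives are recurrent."""
        for r in cohort["records"]:
            lab_rec = contrast_label(r, "recurrence")
            lab_fast = contrast_label(r, "fast_recurrence")
            lab_lethal = contrast_label(r, "lethal")
            if lab_lethal == 1:
                assert lab_fast == 1
            if lab_fast == 1:
                assert lab_rec == 1

    def test_intermediate_psadt_excluded_from_fast_contrast(self):
        from lsrcnv.segment_io import ClinicalRecord

        mid = ClinicalRecord("m", True, 30.0, 8.0, 7, 0.7, 0)
        assert contrast_label(mid, "fast_recurrence") is None
        assert contrast_label(mid, "recurrence") == 1

    def test_short_followup_nonrecurrent_excluded(self):
        from lsrcnv.segment_io import ClinicalRecord

        r = ClinicalRecord("x", False, 50.0, None, 7, 0.7, 0)
        assert contrast_label(r, "recurrence") is None


class TestRunSplit:
    def test_deterministic_under_seed(self, small_cohort):
        data = build_contrast(small_cohort["records"], small_cohort["profiles"], "recurrence")
        a = run_split(data, "LN", seed=42)
        b = run_split(data, "LN", seed=42)
        assert a[0].vector() == pytest.approx(b[0].vector())
        assert a[1].vector() == pytest.approx(b[1].vector())

    def test_metric_invariants(self, small_cohort):
        data = build_contrast(small_cohort["records"], small_cohort["profiles"], "recurrence")
        for sm in run_split(data, "LNFG", seed=9):
            assert 0.0 <= sm.sensitivity <= 1.0
            assert 0.0 <= sm.specificity <= 1.0
            assert 0.0 <= sm.auc <= 1.0
            assert sm.youden == pytest.approx(sm.sensitivity + sm.specificity - 1.0)
            assert sm.balanced_accuracy == pytest.approx(
                (sm.sensitivity + sm.specificity) / 2
            )

    def test_null_cohort_accuracy_near_prevalence(self):
        from lsrcnv import CohortSpec, build_profiles, filter_segments, generate_cohort
        from lsrcnv.synthetic_cohort import CovariateEffects

        spec = CohortSpec(
            n_nonrecurrent=30,
            n_recurrent_fast=15,
            n_recurrent_slow=15,
            size_fold_recurrent=1.0,
            sample_log10_jitter_sd=0.0,
            tail_weight_sd=0.0,
            covariate_effects=CovariateEffects.null(),
            mean_fragments_per_sample=80,
            seed=31,
        )
        segments, records = generate_cohort(spec)
        data = build_contrast(records, build_profiles(filter_segments(segments)), "recurrence")
        _, test = run_split(data, "L", seed=3)
        # max prevalence is 0.5; allow generous Monte-Carlo slack at n=60
        assert abs(test.accuracy - 0.5) < 0.30


class TestTrimmedCV:
    def test_retention_matches_explicit_sort(self, rng):
        sums = list(rng.normal(1.4, 0.2, 14))
        retained = retained_split_indices(sums, trim=2)
        order = sorted(range(14), key=lambda i: (sums[i], i))
        assert retained == sorted(order[2:12])
        assert len(retained) == 10

    def test_trim_zero_is_plain_mean(self, small_cohort):
        data = build_contrast(small_cohort["records"], small_cohort["profiles"], "recurrence")
        cv = trimmed_cv(data, "N", n_repeats=3, trim=0, seed=5)
        assert cv.retained_split_ids == [0, 1, 2]
        manual = np.mean([te.auc for _, te in cv.per_split])
        assert cv.test.auc == pytest.approx(manual)

    def test_identical_repeats_average_to_single_repeat(self):
        sums = [1.0] * 6
        assert retained_split_indices(sums, trim=1) == [1, 2, 3, 4]

    def test_representative_split_is_retained(self, small_cohort):
        data = build_contrast(small_cohort["records"], small_cohort["profiles"], "recurrence")
        cv = trimmed_cv(data, "LN", n_repeats=6, trim=1, seed=8)
        assert cv.representative_split_id in cv.retained_split_ids
        assert len(cv.retained_split_ids) == 4

    def test_summary_table_shape(self, small_cohort):
        data = build_contrast(small_cohort["records"], small_cohort["profiles"], "recurrence")
        cv = trimmed_cv(data, "N", n_repeats=3, trim=0, seed=5)
        table = ev.summary_table({"N": cv})
        assert set(table["role"]) == {"train", "test"}
        assert "auc" in table.columns and len(table) == 2
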