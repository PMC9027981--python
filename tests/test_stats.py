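"""Rank statistics against brute-force enumeration oracles, ROI reduction,
and the cohort report schema."""

import itertools
import json
import math

import numpy as np
import pytest

from acidocest.cest import PHMap, QCMask
from acidocest.stats import (
    SubjectResult,
    cohort_report,
    compare_independent,
    compare_paired,
    normality_check,
    roi_mean_ph,
    spearman_correlation,
    summarize_subject,
)
from acidocest.synthetic import KOOS_SUBSCALES, KoosLinkParams, simulate_cohort


def exact_ranksum_p(a, b):
    """Two-sided rank-sum p by complete enumeration of group assignments."""
    pooled = np.concatenate([a, b])
    ranks = np.argsort(np.argsort(pooled)) + 1.0  # no ties in oracle use
    n = len(a)
    obs = ranks[:n].sum()
    mean = n * (len(pooled) + 1) / 2.0
    stats = [ranks[list(idx)].sum()
             for idx in itertools.combinations(range(len(pooled)), n)]
    dev = abs(obs - mean)
    return np.mean([abs(s - mean) >= dev - 1e-9 for s in stats])


def exact_signedrank_p(d):
    """Two-sided signed-rank p by enumerating all sign patterns."""
    d = np.asarray(d, dtype=float)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    n = len(d)
    mean = n * (n + 1) / 4.0
    dev = abs(w_obs - mean)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mean) >= dev - 1e-9:
            count += 1
    return count / 2 ** n


class TestRoiMean:
    def _maps(self, ph, passed):
        ph = np.asarray(ph, dtype=float)
        passed = np.asarray(passed, dtype=bool)
        qc = QCMask(passed=passed,
                    reject_reason=np.where(passed, 0, 1).astype(np.int8))
        return PHMap(ph=ph, clipped_mask=np.zeros_like(passed)), qc

    def test_uniform_map(self):
        phm, qc = self._maps(np.full((4, 4, 1), 7.0), np.ones((4, 4, 1)))
        rois = np.ones((4, 4, 1), dtype=int)
        assert roi_mean_ph(phm, qc, rois, 1) == (7.0, 16)

    def test_hand_mean(self):
        ph = np.zeros((2, 1, 1))
        ph[0, 0, 0], ph[1, 0, 0] = 6.4, 7.0
        phm, qc = self._maps(ph, np.ones((2, 1, 1)))
        rois = np.ones((2, 1, 1), dtype=int)
        mean, n = roi_mean_ph(phm, qc, rois, 1)
        assert mean == pytest.approx(6.7)
        assert n == 2

    def test_all_failing_roi_is_missing(self):
        phm, qc = self._maps(np.full((3, 1, 1), 7.0), np.zeros((3, 1, 1)))
        rois = np.ones((3, 1, 1), dtype=int)
        assert roi_mean_ph(phm, qc, rois, 1) == (None, 0)

    def test_invariant_to_qc_failing_additions(self):
        ph = np.linspace(6, 8, 8).reshape(8, 1, 1)
        passed = np.array([1, 1, 1, 0, 0, 1, 0, 1], bool).reshape(8, 1, 1)
        phm, qc = self._maps(ph, passed)
        small = np.where(passed, 1, 0)
        big = np.ones_like(small)
        assert roi_mean_ph(phm, qc, small, 1) == roi_mean_ph(phm, qc, big, 1)


class TestRankSum:
    def test_separated_small_groups(self):
        res = compare_independent([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(2 / math.comb(6, 3))

    def test_identical_groups_give_p_one(self):
        res = compare_independent([1.0, 2.0, 3.0], [2.0, 3.0, 1.0])
        assert res.p_value == 1.0

    def test_fully_separated_study_arms(self):
        res = compare_independent(np.arange(7), np.arange(10, 19))
        assert res.p_value == pytest.approx(2 / 11440, rel=1e-9)

    def test_symmetry_under_arm_swap(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(6), rng.random(8)
        assert compare_independent(a, b).p_value == pytest.approx(
            compare_independent(b, a).p_value)

    @pytest.mark.parametrize("n,m", [(2, 3), (3, 3), (4, 5), (6, 7), (7, 7)])
    def test_matches_enumeration_oracle(self, n, m):
        rng = np.random.default_rng(n * 10 + m)
        a = rng.normal(size=n)
        b = rng.normal(loc=0.8, size=m)
        res = compare_independent(a, b)
        assert res.p_value == pytest.approx(exact_ranksum_p(a, b), abs=1e-12)

    def test_empty_arm_rejected(self):
        with pytest.raises(ValueError):
            compare_independent([], [1.0])

    def test_single_subject_arms_warn(self):
        res = compare_independent([6.4], [7.0])
        assert res.p_value == 1.0
        assert res.warning is not None


class TestSignedRank:
    def test_identical_pairs_degenerate(self):
        res = compare_paired([1, 2, 3], [1, 2, 3])
        assert res.p_value == 1.0

    def test_all_positive_differences(self):
        res = compare_paired([2, 3, 4, 5, 6, 7], [1, 2, 3, 4, 5, 6])
        assert res.p_value == pytest.approx(2 / 64)

    def test_single_pair_cannot_reach_significance(self):
        res = compare_paired([2.0], [1.0])
        assert res.p_value == 1.0

    @pytest.mark.parametrize("n", [3, 4, 5, 6, 7])
    def test_matches_enumeration_oracle(self, n):
        rng = np.random.default_rng(n)
        d = rng.normal(loc=0.4, size=n)
        res = compare_paired(d, np.zeros(n))
        assert res.p_value == pytest.approx(exact_signedrank_p(d), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_paired([1, 2], [1, 2, 3])


class TestSpearman:
    def test_monotone_pairs(self):
        rho, _ = spearman_correlation([1, 2, 3, 5], [10, 20, 21, 30])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_correlation([1, 2, 3, 5], [30, 21, 20, 10])
        assert rho == pytest.approx(-1.0)

    def test_worked_four_point_example(self):
        rho, _ = spearman_correlation([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6)

    def test_rank_invariance(self):
        rng = np.random.default_rng(5)
        x, y = rng.random(8), rng.random(8)
        from scipy.stats import rankdata
        r1, p1 = spearman_correlation(x, y)
        r2, p2 = spearman_correlation(rankdata(x), rankdata(y))
        assert r1 == pytest.approx(r2)
        assert p1 == pytest.approx(p2)

    def test_exact_permutation_p_small_n(self):
        # n=4, rho=0.6: count permutations with |rho| >= 0.6 -> 8/24
        rho, p = spearman_correlation([1, 2, 3, 4], [2, 1, 4, 3])
        count = 0
        import itertools as it
        x = np.array([1.0, 2, 3, 4])
        for perm in it.permutations([2, 1, 4, 3]):
            r = np.corrcoef(x, perm)[0, 1]
            if abs(r) >= 0.6 - 1e-12:
                count += 1
        assert p == pytest.approx(count / 24)

    def test_constant_input_flagged(self):
        with pytest.warns(UserWarning):
            rho, p = spearman_correlation([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(rho)


class TestNormality:
    def test_affine_invariance(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=30)
        w1, _ = normality_check(x)
        w2, _ = normality_check(5.0 * x - 3.0)
        assert w1 == pytest.approx(w2, rel=1e-9)

    def test_three_equispaced_points_are_perfectly_normal(self):
        w, _ = normality_check([1.0, 2.0, 3.0])
        assert w == pytest.approx(1.0, abs=1e-6)

    def test_bimodal_sample_rejected(self):
        rng = np.random.default_rng(13)
        x = np.concatenate([rng.normal(-4, 0.2, 25), rng.normal(4, 0.2, 25)])
        _, p = normality_check(x)
        assert p < 0.05

    def test_sample_size_bounds(self):
        with pytest.raises(ValueError):
            normality_check([1.0, 2.0])


class TestCohortReport:
    def _results_from_cohort(self, subjects):
        results = []
        for s in subjects:
            means = {lab: s.phantom.ph_by_tissue[lab] for lab in (1, 2, 3)}
            results.append(SubjectResult(
                subject_id=s.record.subject_id, group=s.record.group,
                mean_ph=means, voxel_counts={1: 50, 2: 30, 3: 40},
                overall_mean_ph=s.true_mean_ph, overall_count=120))
        return results

    def test_report_schema_and_perfect_correlations(self, tmp_path):
        link = KoosLinkParams(koos_noise_sd=0.0, vaps_noise_sd=0.0)
        subjects = simulate_cohort(seed=1, koos_link=link,
                                   generate_images=False)
        report = cohort_report(self._results_from_cohort(subjects),
                               [s.record for s in subjects], tmp_path)
        assert len(report["correlations"]) == 7
        for row in report["correlations"]:
            want = -1.0 if row["score"] == "vaps" else 1.0
            assert row["rho"] == pytest.approx(want)
        assert len(report["contrasts"]) == 1 + 3 + 2 * 3
        assert (tmp_path / "subjects.csv").exists()
        assert (tmp_path / "contrasts.json").exists()
        assert (tmp_path / "correlations.json").exists()
        assert (tmp_path / "boxplots_ph_by_group.png").exists()
        assert (tmp_path / "scatter_ph_vs_scores.png").exists()
        payload = json.loads((tmp_path / "contrasts.json").read_text())
        assert {c["contrast"] for c in payload["contrasts"]} >= {
            "all_rois:no_oa_vs_oa", "cartilage:no_oa_vs_oa",
            "oa:cartilage_vs_meniscus"}

    def test_single_subject_per_group_warns(self, tmp_path):
        subjects = simulate_cohort(n_no_oa=1, n_oa=1, seed=4,
                                   generate_images=False)
        report = cohort_report(self._results_from_cohort(subjects),
                               [s.record for s in subjects], tmp_path,
                               make_figures=False)
        head = report["contrasts"][0]
        assert head["p_value"] == 1.0
        assert head["warning"] is not None

    def test_summarize_subject_reduces_maps(self, tmp_path):
        subjects = simulate_cohort(n_no_oa=1, n_oa=1, seed=6,
                                   generate_images=False)
        s = subjects[0]
        shape = s.phantom.labels.shape
        ph = np.where(s.phantom.labels > 0, 7.0, np.nan)
        qc = QCMask(passed=s.phantom.labels > 0,
                    reject_reason=np.where(s.phantom.labels > 0, 0, 3).astype(np.int8))
        res = summarize_subject(s.record, PHMap(ph, np.zeros(shape, bool)), qc,
                                s.phantom.labels)
        assert res.overall_mean_ph == pytest.approx(7.0)
        assert all(res.mean_ph[lab] == pytest.approx(7.0) for lab in (1, 2, 3))
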