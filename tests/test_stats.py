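"""Statistical battery: exact small-sample tests, FDR, summaries."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from scfc.core import ConnectivityMatrix, Parcellation
from scfc.stats import (
    DegenerateDataError,
    age_correlation,
    analytical_shuffle_scorer,
    band_variability_comparison,
    bh_fdr,
    cohens_d,
    edge_variability,
    exact_label_permutation,
    group_comparison_records,
    mannwhitney,
    matrix_cohort_similarity,
    model_comparison,
    paired_ttest_weights,
    pearson_edges,
    shuffle_individuality,
    spearman_exact,
    spearman_panss,
    total_strength,
)

from _oracles import brute_mannwhitney_p, brute_spearman


def _fc(values, parc=None):
    parc = parc or Parcellation.generic(values.shape[0])
    return ConnectivityMatrix(values=values, kind="FC", variant="alpha",
                              parcellation=parc)


class TestPearsonEdges:
    def test_identity_and_negation(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(6, 6))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0)
        m = _fc(vals)
        assert pearson_edges(m, m) == pytest.approx(1.0)
        assert pearson_edges(m, _fc(-vals)) == pytest.approx(-1.0)

    def test_constant_rejected(self):
        m = _fc(np.ones((4, 4)) - np.eye(4))
        with pytest.raises(DegenerateDataError):
            pearson_edges(m, m)

    def test_independent_edges_rarely_exceed_point_one(self):
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(500):
            x, y = rng.normal(size=(2, 3486))
            hits += abs(np.corrcoef(x, y)[0, 1]) < 0.1
        assert hits / 500 >= 0.99


class TestCohensD:
    def test_identical_groups_zero(self):
        assert cohens_d([1, 2, 3, 4], [1, 2, 3, 4]) == 0.0

    def test_one_pooled_sd_apart(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=2000)
        sd = np.sqrt(a.var(ddof=1))
        assert cohens_d(a + sd, a) == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_example(self):
        assert cohens_d([1, 2, 3], [3, 4, 5]) == pytest.approx(-2.0)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(DegenerateDataError):
            cohens_d([1.0, 1.0], [2.0, 2.0])


class TestMannWhitney:
    def test_equal_samples_give_p_one(self):
        with pytest.warns(UserWarning, match="ties"):
            res = mannwhitney([1.0, 2, 3, 4, 5], [1.0, 2, 3, 4, 5])
        assert res.p_value == pytest.approx(1.0)
        assert res.method == "asymptotic"

    def test_complete_separation_exact_p(self):
        res = mannwhitney([1, 2, 3, 4, 5.0], [6, 7, 8, 9, 10.0])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 252)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            a = rng.normal(size=4)
            b = rng.normal(size=5)
            res = mannwhitney(a, b)
            assert res.p_value == pytest.approx(brute_mannwhitney_p(a, b))

    def test_large_unbalanced_groups_effect_size(self):
        rng = np.random.default_rng(3)
        ds = [
            mannwhitney(rng.normal(1, 1, 5), rng.normal(0, 1, 101)).cohens_d
            for _ in range(30)
        ]
        assert abs(np.mean(ds) - 1.0) < 0.5

    def test_empty_group_rejected(self):
        with pytest.raises(DegenerateDataError):
            mannwhitney([], [1.0])


class TestLabelPermutation:
    def test_one_sided_minimum_p_is_1_over_252(self):
        res = exact_label_permutation(
            [1, 2, 3, 4, 5.0], [6, 7, 8, 9, 10.0], sided="one"
        )
        # a below b, one-sided tests mean(a) > mean(b): flip for the minimum
        res_flip = exact_label_permutation(
            [6, 7, 8, 9, 10.0], [1, 2, 3, 4, 5.0], sided="one"
        )
        assert res_flip.p_value == pytest.approx(1 / 252)
        assert res.p_value == pytest.approx(1.0)
        assert res.exact and res.n_permutations == 252

    def test_identical_groups_p_one(self):
        res = exact_label_permutation([1.0, 2, 3], [1.0, 2, 3], sided="two")
        assert res.p_value == pytest.approx(1.0)

    def test_attainable_p_values_are_grid_multiples(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            res = exact_label_permutation(
                rng.normal(size=5), rng.normal(size=5), sided="two"
            )
            assert (res.p_value * 252) == pytest.approx(round(res.p_value * 252))
            assert res.p_value >= 1 / 252

    def test_monte_carlo_fallback_seeded(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=12), rng.normal(size=13)  # C(25,12) too large
        r1 = exact_label_permutation(a, b, seed=9, n_monte_carlo=2000)
        r2 = exact_label_permutation(a, b, seed=9, n_monte_carlo=2000)
        assert not r1.exact
        assert r1.p_value == r2.p_value > 0


class TestSpearman:
    def test_monotone_relationship(self):
        rho, p = spearman_exact([1, 2, 3, 4, 5], [2, 4, 9, 16, 30])
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 120)  # both perfect orderings

    def test_matches_brute_force_with_ties(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0])
        y = np.array([5.0, 3.0, 4.0, 4.0, 1.0])
        rho, p = spearman_exact(x, y)
        rho_b, p_b = brute_spearman(x, y)
        assert rho == pytest.approx(rho_b)
        assert p == pytest.approx(p_b)

    def test_too_few_observations(self):
        with pytest.raises(DegenerateDataError):
            spearman_exact([1, 2], [2, 1])


class TestBhFdr:
    def test_hand_stepped_example(self):
        res = bh_fdr([0.005, 0.01, 0.03, 0.04], alpha=0.05)
        assert res.significant.all()
        assert res.threshold == pytest.approx(0.04)

    def test_no_rejections(self):
        res = bh_fdr([0.9, 0.8])
        assert not res.significant.any() and res.threshold is None

    def test_single_p_reduces_to_raw_alpha(self):
        res = bh_fdr([0.04], alpha=0.05)
        assert res.significant.all() and res.threshold == pytest.approx(0.04)

    def test_flags_monotone_and_match_statsmodels(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            p = rng.uniform(1e-6, 1, size=rng.integers(2, 30))
            res = bh_fdr(p, alpha=0.05)
            # monotone: every p below a flagged p is flagged
            if res.significant.any():
                assert res.significant[p <= res.threshold].all()
            reference = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            np.testing.assert_array_equal(res.significant, reference)

    def test_by_variant_is_more_conservative(self):
        p = [0.01, 0.02, 0.03, 0.04, 0.05]
        assert bh_fdr(p, variant="by").significant.sum() <= bh_fdr(p).significant.sum()

    def test_invalid_p_rejected(self):
        with pytest.raises(Exception):
            bh_fdr([0.0, 0.5])


class TestRecordLevelAnalyses:
    @staticmethod
    def _records(rs, band="alpha", weight="FA", model="analytical"):
        return pd.DataFrame(
            {
                "subject": [f"s{i}" for i in range(len(rs))],
                "model": model,
                "band": band,
                "weight": weight,
                "r": rs,
            }
        )

    def test_paired_ttest_degenerate_on_identical_columns(self):
        rng = np.random.default_rng(0)
        rs = rng.uniform(0.3, 0.9, 20)
        recs = pd.concat(
            [self._records(rs, weight="FA"), self._records(rs, weight="iRD")]
        )
        with pytest.raises(DegenerateDataError):
            paired_ttest_weights(recs, "alpha", "FA", "iRD")

    def test_paired_ttest_detects_shift(self):
        rng = np.random.default_rng(1)
        rs = rng.uniform(0.3, 0.6, 126)
        shifted = rs + 0.1 + rng.normal(0, 0.05, 126)
        recs = pd.concat(
            [self._records(rs, weight="FA"), self._records(shifted, weight="iRD")]
        )
        assert paired_ttest_weights(recs, "alpha", "FA", "iRD") < 1e-6

    def test_age_correlation_perfect_line(self):
        ages = {f"s{i}": 20 + i for i in range(20)}
        rs = np.array([0.9 - 0.01 * i for i in range(20)])
        df = age_correlation(self._records(rs), ages)
        assert df.r.iloc[0] == pytest.approx(-1.0)
        assert df.significant.iloc[0]

    def test_age_correlation_constant_ages_rejected(self):
        with pytest.raises(DegenerateDataError):
            age_correlation(self._records(np.linspace(0.2, 0.8, 10)),
                            {f"s{i}": 30 for i in range(10)})

    def test_group_comparison_flags_separated_groups(self):
        recs = self._records(
            np.concatenate([np.linspace(0.7, 0.9, 20), np.linspace(0.2, 0.4, 5)])
        )
        groups = {f"s{i}": "healthy" if i < 20 else "psychosis" for i in range(25)}
        df = group_comparison_records(recs, groups)
        assert df.significant.all()
        assert df.cohens_d.iloc[0] > 0.8

    def test_spearman_panss_perfect_monotone(self):
        from scfc.core import PanssScores

        rs = np.array([0.9, 0.8, 0.7, 0.6, 0.5])  # error increases
        panss = {
            f"s{i}": PanssScores(37 + 5 * i, 9, 8, 20 + 5 * i)
            for i in range(5)
        }
        df = spearman_panss(self._records(rs), panss)
        assert df.rho.iloc[0] == pytest.approx(1.0)

    def test_model_comparison_uses_exact_enumeration(self):
        ra = self._records(np.linspace(0.8, 0.9, 5), model="gmha")
        rb = self._records(np.linspace(0.2, 0.3, 5), model="analytical")
        df = model_comparison(ra, rb, sided="one")
        assert df.p.iloc[0] == pytest.approx(1 / 252)
        assert df.exact.all()


class TestShuffling:
    def test_identical_subjects_make_shuffling_a_noop(self):
        score = lambda donor, target: 0.5  # same r whoever the donor is
        df = shuffle_individuality([f"s{i}" for i in range(6)], score,
                                   n_perm=10, seed=0)
        np.testing.assert_allclose(df.r_shuffled_mean, df.r_unshuffled)

    def test_analytical_scorer_diagonal_matches_direct_fit(self, small_cohort):
        from scfc.analytical import predict_cohort

        scorer = analytical_shuffle_scorer(small_cohort, "FA", "alpha")
        direct = predict_cohort(small_cohort, weights=["FA"], bands=["alpha"])
        for sid in [s.id for s in small_cohort.subjects][:3]:
            expected = direct[direct.subject == sid].r.iloc[0]
            assert scorer(sid, sid) == pytest.approx(expected)

    def test_nperm_validated(self):
        with pytest.raises(Exception):
            shuffle_individuality(["a", "b"], lambda d, t: 0.0, n_perm=0)


class TestMatrixSummaries:
    def test_similarity_of_member_is_one(self):
        rng = np.random.default_rng(2)
        mats = {}
        for sid in "abc":
            v = rng.normal(size=(5, 5))
            v = (v + v.T) / 2
            np.fill_diagonal(v, 0)
            mats[sid] = _fc(v, Parcellation.generic(5))
        df = matrix_cohort_similarity(mats["a"], mats)
        assert df[df.cohort_subject == "a"].r.iloc[0] == pytest.approx(1.0)
        assert df.healthy_reference.nunique() == 1

    def test_total_strength_sum_and_linearity(self):
        vals = np.array([[0, 1.0, 2], [1, 0, 3], [2, 3, 0]])
        m = _fc(vals)
        assert total_strength(m) == 6.0
        assert total_strength(_fc(2 * vals)) == 12.0

    def test_edge_variability_zero_for_identical_subjects(self, noiseless_cohort):
        # zero noise + zero individuality: across-subject SDs are tiny
        sds = edge_variability(noiseless_cohort, "alpha")
        assert np.median(sds) < 0.05

    def test_variability_scale_invariance(self, small_cohort):
        medians, _ = band_variability_comparison(small_cohort)
        # max-normalization first => doubling all matrices changes nothing;
        # check the delta > beta ordering the generator plants
        by_band = medians.set_index("band").median_sd
        assert by_band["delta"] > by_band["beta"]
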