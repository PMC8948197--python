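import itertools
import math

import numpy as np
import pandas as pd
import pytest

from pathflux import (
    compare_classifiers_bootstrap,
    compute_flux_matrix,
    compute_im_index,
    differential_pathway_flux,
    kruskal_wallis,
    logistic_odds_ratio,
    roc_with_bootstrap,
    spearman_matrix,
    wilcoxon_two_group,
)
from pathflux.flux import FluxMatrix
from pathflux.stats import auc_midrank


def make_flux_matrix(sig, met, samples=None):
    """FluxMatrix with one signaling and one metabolic pathway column."""
    samples = samples or [f"s{i}" for i in range(len(sig))]
    df = pd.DataFrame({"PSIG": sig, "PMET": met}, index=samples)
    return FluxMatrix(
        df, {"PSIG": "signaling_transduction", "PMET": "energy_metabolism"}
    )


class TestIMIndex:
    def test_zero_weights_annihilate(self):
        fm = make_flux_matrix([10.0], [5.0])
        t = compute_im_index(fm, alpha=0.0, beta=0.0)
        assert t.data["im_index"].tolist() == [0.0]

    def test_default_weights_sum_both_classes(self):
        fm = make_flux_matrix([10.0], [5.0])
        assert compute_im_index(fm).data["im_index"].iloc[0] == pytest.approx(15.0)

    def test_weighted_sum(self):
        fm = make_flux_matrix([10.0], [5.0])
        t = compute_im_index(fm, alpha=2.0, beta=1.0)
        assert t.data["im_index"].iloc[0] == pytest.approx(25.0)
        assert (t.alpha, t.beta) == (2.0, 1.0)

    def test_linearity_in_weights(self):
        rng = np.random.default_rng(5)
        fm = make_flux_matrix(rng.normal(size=6), rng.normal(size=6))
        a1, a2, b = 0.7, 1.9, 0.4
        combined = compute_im_index(fm, alpha=a1 + a2, beta=b).scores
        split = (
            compute_im_index(fm, alpha=a1, beta=b).scores
            + compute_im_index(fm, alpha=a2, beta=0.0).scores
        )
        pd.testing.assert_series_equal(combined, split, rtol=1e-12)

    def test_missing_klass_is_an_error(self):
        fm = make_flux_matrix([1.0], [2.0])
        del fm.klass_of["PMET"]
        with pytest.raises(ValueError, match="PMET"):
            compute_im_index(fm)

    def test_labels_attached_and_checked(self):
        fm = make_flux_matrix([1.0, 2.0], [0.0, 0.0])
        t = compute_im_index(fm, labels={"s0": "benign", "s1": "malignant"})
        assert t.data["group"].tolist() == ["benign", "malignant"]
        with pytest.raises(ValueError, match="s1"):
            compute_im_index(fm, labels={"s0": "benign"})


def kw_brute_force(groups):
    """Kruskal-Wallis H via the rank-sum formula with tie correction."""
    import scipy.stats

    x = np.concatenate(groups)
    n = len(x)
    ranks = scipy.stats.rankdata(x)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(x, return_counts=True)
    tie = 1 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie


class TestKruskalWallis:
    def test_all_identical_values_return_h0_p1(self):
        h, p = kruskal_wallis([2.0] * 9, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert (h, p) == (0.0, 1.0)

    def test_matches_brute_force_rank_formula(self):
        groups = [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]
        labels = ["a", "a", "b", "b", "c", "c"]
        h, p = kruskal_wallis(list(itertools.chain(*groups)), labels)
        assert h == pytest.approx(kw_brute_force(groups), rel=1e-12)

    def test_brute_force_with_ties(self):
        groups = [[1.0, 1.0, 2.0], [2.0, 3.0], [3.0, 3.0, 5.0]]
        labels = ["a"] * 3 + ["b"] * 2 + ["c"] * 3
        h, _ = kruskal_wallis(list(itertools.chain(*groups)), labels)
        assert h == pytest.approx(kw_brute_force(groups), rel=1e-12)

    def test_group_relabeling_invariance(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        h1, p1 = kruskal_wallis(x, ["a", "a", "b", "b", "c", "c"])
        h2, p2 = kruskal_wallis(x, ["c", "c", "a", "a", "b", "b"])
        assert (h1, p1) == (h2, p2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1.0, 2.0], ["a", "a"])


def wilcoxon_exact_enumeration(a, b):
    """Two-sided exact p by enumerating all rank assignments (no ties)."""
    import scipy.stats

    x = np.asarray(list(a) + list(b), dtype=float)
    ranks = scipy.stats.rankdata(x)
    n1 = len(a)
    n1n2 = len(a) * len(b)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for idx in itertools.combinations(range(len(x)), n1):
        r = ranks[list(idx)]
        us.append(r.sum() - n1 * (n1 + 1) / 2)
    us = np.asarray(us)
    dev = abs(u_obs - n1n2 / 2)
    return float(np.mean(np.abs(us - n1n2 / 2) >= dev - 1e-12))


class TestWilcoxon:
    def test_identical_distributions_give_p1(self):
        w, p = wilcoxon_two_group(
            [1.0, 2.0, 3.0, 1.0, 2.0, 3.0], ["a"] * 3 + ["b"] * 3
        )
        assert p == pytest.approx(1.0)

    def test_extreme_separation_matches_exact_enumeration(self):
        a, b = [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]
        w, p = wilcoxon_two_group(a + b, ["a"] * 3 + ["b"] * 3)
        assert w in (0.0, 9.0)  # U at its extreme
        assert p == pytest.approx(wilcoxon_exact_enumeration(a, b))
        assert p == pytest.approx(0.1)

    def test_moderate_case_matches_exact_enumeration(self):
        a, b = [1.0, 4.0, 6.0], [2.0, 5.0, 7.0, 8.0]
        _, p = wilcoxon_two_group(a + b, ["a"] * 3 + ["b"] * 4)
        assert p == pytest.approx(wilcoxon_exact_enumeration(a, b))

    def test_label_swap_symmetry(self):
        x = [1.0, 5.0, 2.0, 7.0, 3.0]
        _, p1 = wilcoxon_two_group(x, ["a", "a", "b", "b", "b"])
        _, p2 = wilcoxon_two_group(x, ["b", "b", "a", "a", "a"])
        assert p1 == pytest.approx(p2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_two_group([1.0, 2.0], ["a", "a"])


class TestAUC:
    def test_perfect_separation(self):
        assert auc_midrank([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_worked_example(self):
        assert auc_midrank([1, 3, 2, 4], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_equals_mann_whitney_u_on_random_instances(self):
        import scipy.stats

        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            scores = rng.integers(0, 6, size=n).astype(float)  # many ties
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            u = scipy.stats.mannwhitneyu(
                scores[y == 1], scores[y == 0], alternative="two-sided"
            ).statistic
            n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
            assert auc_midrank(scores, y) == pytest.approx(u / (n_pos * n_neg))

    def test_negation_flips_auc(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=30)
        y = rng.integers(0, 2, size=30)
        y[0], y[1] = 0, 1
        assert auc_midrank(scores, y) == pytest.approx(1 - auc_midrank(-scores, y))


class TestROCBootstrap:
    def test_summary_invariants_and_determinism(self):
        rng = np.random.default_rng(3)
        scores = np.concatenate([rng.normal(0, 1, 20), rng.normal(1, 1, 15)])
        labels = np.array([0] * 20 + [1] * 15)
        r1 = roc_with_bootstrap(scores, labels, n_boot=500, seed=9)
        r2 = roc_with_bootstrap(scores, labels, n_boot=500, seed=9)
        assert r1 == r2
        assert 0.0 <= r1.ci_low <= r1.auc <= r1.ci_high <= 1.0
        assert (r1.n_pos, r1.n_neg) == (15, 20)
        r3 = roc_with_bootstrap(scores, labels, n_boot=500, seed=10)
        assert r3.ci_low != r1.ci_low  # different seed, different resamples

    def test_perfectly_separated_scores(self):
        r = roc_with_bootstrap([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1],
                               n_boot=200, seed=0)
        assert r.auc == 1.0
        assert r.ci_high == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_with_bootstrap([1.0, 2.0], [1, 1], n_boot=10, seed=0)


class TestCompareClassifiers:
    def test_identical_scores_give_p1(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        cmp_res = compare_classifiers_bootstrap(scores, scores, y, n_boot=200, seed=1)
        assert cmp_res.p_one_sided == pytest.approx(1.0)
        assert cmp_res.auc_index == cmp_res.auc_other

    def test_extreme_advantage_is_significant(self):
        rng = np.random.default_rng(0)
        n = 40
        y = np.array([0] * 20 + [1] * 20)
        index = y + rng.normal(0, 1e-3, n)  # perfect separator
        other = -y + rng.normal(0, 1e-3, n)  # anti-separator
        cmp_res = compare_classifiers_bootstrap(index, other, y, n_boot=2000, seed=1)
        assert cmp_res.auc_index == 1.0
        assert cmp_res.p_one_sided <= 0.05

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(4)
        y = np.array([0] * 15 + [1] * 15)
        a = rng.normal(y, 1.0)
        b = rng.normal(y, 2.0)
        p1 = compare_classifiers_bootstrap(a, b, y, n_boot=300, seed=7).p_one_sided
        p2 = compare_classifiers_bootstrap(
            np.exp(a), 3 * b - 10, y, n_boot=300, seed=7
        ).p_one_sided
        assert p1 == p2

    def test_mismatched_sample_sets_rejected(self):
        with pytest.raises(ValueError):
            compare_classifiers_bootstrap(
                [1.0, 2.0], [1.0, 2.0, 3.0], [0, 1], n_boot=10, seed=0
            )


class TestLogisticOR:
    def test_binary_score_matches_cross_product_ratio(self):
        # score=1: 8 pos / 2 neg; score=0: 2 pos / 8 neg -> OR (8*8)/(2*2)=16
        score = [1.0] * 10 + [0.0] * 10
        y = [1] * 8 + [0] * 2 + [1] * 2 + [0] * 8
        res = logistic_odds_ratio(score, y, pos_label=1)
        assert res.odds_ratio == pytest.approx(16.0, abs=1e-6)
        assert res.ci_low < 16.0 < res.ci_high
        assert not res.separation and not res.degenerate

    def test_constant_score_flagged_degenerate(self):
        res = logistic_odds_ratio([2.0] * 8, [0, 1] * 4)
        assert res.degenerate
        assert math.isnan(res.odds_ratio)

    def test_complete_separation_flagged_with_infinite_or(self):
        res = logistic_odds_ratio(
            [1.0, 2.0, 3.0, 10.0, 11.0, 12.0], [0, 0, 0, 1, 1, 1], pos_label=1
        )
        assert res.separation
        assert res.odds_ratio == math.inf

    def test_shift_invariance_of_per_unit_or(self):
        rng = np.random.default_rng(11)
        y = np.array([0] * 20 + [1] * 20)
        x = rng.normal(y * 0.8, 1.0)
        r1 = logistic_odds_ratio(x, y, pos_label=1)
        r2 = logistic_odds_ratio(x + 100.0, y, pos_label=1)
        assert r1.odds_ratio == pytest.approx(r2.odds_ratio, rel=1e-6)

    def test_missing_scores_dropped(self):
        x = [np.nan, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 1.0, 0.0]
        y = [1, 1, 0, 1, 0, 1, 0, 1, 0, 0, 1, 1]
        res = logistic_odds_ratio(x, y, pos_label=1)
        assert math.isfinite(res.odds_ratio)


class TestSpearman:
    def test_monotone_transform_gives_rho_one(self):
        s = pd.Series([1.0, 5.0, 2.0, 9.0], index=list("abcd"))
        cov = pd.DataFrame({"biomarker": np.exp(s)})
        out = spearman_matrix(s, cov)
        assert out.loc["biomarker", "rho"] == pytest.approx(1.0)

    def test_negation_gives_rho_minus_one(self):
        s = pd.Series([1.0, 5.0, 2.0, 9.0], index=list("abcd"))
        out = spearman_matrix(s, pd.DataFrame({"neg": -s}))
        assert out.loc["neg", "rho"] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson(self):
        import scipy.stats

        rng = np.random.default_rng(13)
        s = pd.Series(rng.normal(size=12), index=[f"s{i}" for i in range(12)])
        cov = pd.DataFrame({"c": rng.normal(size=12)}, index=s.index)
        rho = spearman_matrix(s, cov).loc["c", "rho"]
        expected = np.corrcoef(
            scipy.stats.rankdata(s), scipy.stats.rankdata(cov["c"])
        )[0, 1]
        assert rho == pytest.approx(expected, rel=1e-12)

    def test_short_columns_skipped_with_warning(self):
        s = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        cov = pd.DataFrame({"sparse": [1.0, np.nan, np.nan]}, index=s.index)
        with pytest.warns(UserWarning, match="sparse"):
            out = spearman_matrix(s, cov)
        assert "sparse" not in out.index


class TestDifferentialFlux:
    def test_single_pathway_bonferroni_is_identity(self):
        fm = FluxMatrix(
            pd.DataFrame({"P": [1.0, 2.0, 5.0, 6.0]}, index=list("abcd")),
            {"P": "signaling_transduction"},
        )
        labels = {"a": "x", "b": "x", "c": "y", "d": "y"}
        out = differential_pathway_flux(fm, labels)
        assert out.loc[0, "p_bonferroni"] == pytest.approx(out.loc[0, "p_raw"])

    def test_bonferroni_multiplies_by_pathway_count(self):
        rng = np.random.default_rng(21)
        m = 43
        df = pd.DataFrame(
            rng.normal(size=(12, m)),
            index=[f"s{i}" for i in range(12)],
            columns=[f"P{i}" for i in range(m)],
        )
        fm = FluxMatrix(df, {c: "signaling_transduction" for c in df.columns})
        labels = {f"s{i}": ("x" if i < 6 else "y") for i in range(12)}
        out = differential_pathway_flux(fm, labels)
        expect = np.minimum(1.0, out["p_raw"] * m)
        np.testing.assert_allclose(out["p_bonferroni"], expect)
        assert out["p_raw"].is_monotonic_increasing

    def test_driver_pathway_ranks_first_on_synthetic_cohort(self):
        from pathflux import CohortSpec, NetworkSpec, generate_cohort, generate_network

        net = generate_network(NetworkSpec(seed=2))
        mat, labels, truth = generate_cohort(
            net,
            CohortSpec(
                group_sizes={"malignant": 15, "benign": 15, "control": 15},
                seed=2,
            ),
        )
        fm = compute_flux_matrix(mat, net)
        out = differential_pathway_flux(fm, labels)
        assert out.loc[0, "pathway_id"] == truth["driver_pathways"][0]
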