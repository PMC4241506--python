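"""PSR selection, cut-points, KM/log-rank, odds ratios and AUC."""
import numpy as np
import pandas as pd
import pytest

from erlnc.prognosis import (ConvergenceError, SurvivalCohort, auc_ci,
                             evaluate_marker, km_estimate, logrank_test,
                             multivariable_or, optimal_cutpoint, or_from_table,
                             select_psr, univariable_or)
from erlnc.simulate import SimConfig, gen_cohort


def logrank_oracle(ta, ea, tb, eb):
    """O-E/V log-rank chi-square over pooled event times, computed directly."""
    ta, ea = np.asarray(ta, float), np.asarray(ea, int)
    tb, eb = np.asarray(tb, float), np.asarray(eb, int)
    times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    O = E = V = 0.0
    for t in times:
        na = np.sum(ta >= t)
        nb = np.sum(tb >= t)
        da = np.sum((ta == t) & (ea == 1))
        db = np.sum((tb == t) & (eb == 1))
        n, d = na + nb, da + db
        O += da
        E += d * na / n
        if n > 1:
            V += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


class TestSelectPsr:
    def test_zero_variance_psr_wins(self):
        mat = pd.DataFrame({"s1": [1.0, 1.0, 3.0, 5.0], "s2": [2.0, 2.0, 1.0, 9.0]},
                           index=["p1", "p2", "p3", "p4"])
        mapping = {"p1": "psrA", "p2": "psrA", "p3": "psrB", "p4": "psrB"}
        assert select_psr(mat, mapping) == "psrA"

    def test_low_noise_psr_selected(self):
        rng = np.random.default_rng(0)
        n_samples = 50
        signal = rng.normal(10, 2, n_samples)
        rows = {f"a{i}": signal + rng.normal(0, 1.0, n_samples) for i in range(4)}
        rows.update({f"b{i}": signal + rng.normal(0, 0.1, n_samples) for i in range(4)})
        mat = pd.DataFrame(rows).T
        mapping = {f"a{i}": "noisy" for i in range(4)}
        mapping.update({f"b{i}": "quiet" for i in range(4)})
        assert select_psr(mat, mapping) == "quiet"

    def test_single_psr_returned_unconditionally(self):
        mat = pd.DataFrame({"s1": [1.0]}, index=["p"])
        assert select_psr(mat, {"p": "only"}) == "only"

    def test_empty_matrix_raises(self):
        with pytest.raises(ValueError):
            select_psr(pd.DataFrame(), {})


class TestOptimalCutpoint:
    def test_perfect_separation(self):
        res = optimal_cutpoint([1, 2, 3, 4], [0, 0, 1, 1])
        assert (res.cut, res.sensitivity, res.specificity, res.product) == \
            (2.5, 1.0, 1.0, 1.0)

    def test_anti_informative_scores_pick_lowest_tied_cut(self):
        # every candidate cut has sens*spec = 0; the tie goes to the lowest
        res = optimal_cutpoint([1, 2, 3, 4], [1, 1, 0, 0])
        assert res.product == pytest.approx(0.0)
        assert res.cut == 1.5

    def test_all_equal_scores_raise(self):
        with pytest.raises(ValueError):
            optimal_cutpoint([5, 5, 5], [0, 1, 0])

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            optimal_cutpoint([1, 2, 3], [1, 1, 1])

    @pytest.mark.parametrize("seed", range(5))
    def test_maximizes_over_exhaustive_candidates(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        scores = rng.normal(size=n)
        labels = (rng.random(n) < 0.4).astype(int)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        res = optimal_cutpoint(scores, labels)
        uniq = np.unique(scores)
        pos, neg = labels == 1, labels == 0
        for cut in (uniq[:-1] + uniq[1:]) / 2:
            pred = scores >= cut
            prod = (np.sum(pred & pos) / pos.sum()) * (np.sum(~pred & neg) / neg.sum())
            assert res.product >= prod - 1e-12


class TestKaplanMeier:
    def test_three_uncensored_events(self):
        km = km_estimate([1, 2, 3], [1, 1, 1])
        assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        assert np.allclose(km.at_risk, [3, 2, 1])

    def test_all_censored_stays_at_one(self):
        km = km_estimate([1, 2, 3], [0, 0, 0])
        assert km.event_times.size == 0
        assert km.survival_at(5.0) == 1.0

    def test_censoring_between_events(self):
        km = km_estimate([1, 2, 3], [1, 0, 1])
        assert km.survival_at(1) == pytest.approx(2 / 3)
        assert km.survival_at(3) == pytest.approx(0.0)  # 2/3 * (1 - 1/1)

    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(5.0, 100)
        km = km_estimate(times, np.ones(100, dtype=int))
        for t in np.quantile(times, [0.1, 0.5, 0.9]):
            ecdf = np.mean(times <= t)
            assert km.survival_at(t) == pytest.approx(1 - ecdf, abs=1e-12)

    def test_negative_time_raises(self):
        with pytest.raises(ValueError):
            km_estimate([-1, 2], [1, 1])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        g = ([1, 2, 3, 4], [1, 1, 1, 1])
        res = logrank_test(g, g)
        assert res["chi_square"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_three_vs_three_matches_hand_table(self):
        # A: events at 1,2,3; B: events at 4,5,6 -> O_A=3, E_A=1.15, V=0.6775
        res = logrank_test(([1, 2, 3], [1, 1, 1]), ([4, 5, 6], [1, 1, 1]))
        assert res["chi_square"] == pytest.approx(1.85 ** 2 / 0.6775, rel=1e-6)

    def test_matches_direct_oracle_with_censoring(self):
        rng = np.random.default_rng(6)
        ta, tb = rng.exponential(3, 40), rng.exponential(5, 35)
        ea, eb = (rng.random(40) < 0.7).astype(int), (rng.random(35) < 0.7).astype(int)
        res = logrank_test((ta, ea), (tb, eb))
        assert res["chi_square"] == pytest.approx(logrank_oracle(ta, ea, tb, eb),
                                                  rel=1e-6)

    def test_label_swap_invariance(self):
        a, b = ([1, 3, 5], [1, 1, 0]), ([2, 4, 6], [1, 0, 1])
        assert logrank_test(a, b)["chi_square"] == \
            pytest.approx(logrank_test(b, a)["chi_square"])

    def test_no_events_raises(self):
        with pytest.raises(ValueError):
            logrank_test(([1, 2], [0, 0]), ([3], [0]))


class TestOddsRatios:
    def test_balanced_table_or_one(self):
        assert or_from_table(10, 10, 10, 10)["or"] == pytest.approx(1.0)

    def test_four_fold_table(self):
        assert or_from_table(20, 10, 10, 20)["or"] == pytest.approx(4.0)

    def test_zero_cell_is_finite_via_haldane(self):
        res = or_from_table(5, 0, 3, 7)
        assert np.isfinite(res["or"]) and res["or"] > 1

    def test_empty_margin_raises(self):
        with pytest.raises(ValueError):
            or_from_table(0, 0, 5, 5)

    def test_univariable_from_vectors(self):
        exposure = [1] * 30 + [0] * 30
        outcome = [1] * 20 + [0] * 10 + [1] * 10 + [0] * 20
        res = univariable_or(exposure, outcome)
        assert res["or"] == pytest.approx(4.0)
        assert res["ci_low"] < 4.0 < res["ci_high"]


def _cohort_from_binary(y, marker_high, extra=None):
    n = len(y)
    table = pd.DataFrame({
        "id": [f"p{i}" for i in range(n)],
        "marker_expression": np.asarray(marker_high, float),
        "time_bcr": np.ones(n), "event_bcr": y,
        "time_met": np.ones(n), "event_met": 0,
        "event_pcsm": 0, "gs_gt7": 0})
    if extra:
        for k, v in extra.items():
            table[k] = v
    return SurvivalCohort(table)


class TestMultivariableOR:
    def test_marker_only_reproduces_contingency_or(self):
        rng = np.random.default_rng(1)
        high = (rng.random(400) < 0.5).astype(int)
        y = (rng.random(400) < np.where(high, 0.6, 0.3)).astype(int)
        cohort = _cohort_from_binary(y, high)
        table = multivariable_or(cohort, "bcr", high)
        uni = univariable_or(high, y)
        # logistic with a single binary regressor equals the 2x2 OR (4 s.f.)
        assert table.loc[0, "or"] == pytest.approx(uni["or"], rel=1e-4)

    def test_independent_covariate_leaves_marker_or(self):
        rng = np.random.default_rng(3)
        n = 2000
        high = (rng.random(n) < 0.5).astype(int)
        y = (rng.random(n) < np.where(high, 0.55, 0.3)).astype(int)
        cov = (rng.random(n) < 0.4).astype(int)
        cohort = _cohort_from_binary(y, high, extra={"LNI": cov})
        adj = multivariable_or(cohort, "bcr", high, covariates=["LNI"])
        uni = univariable_or(high, y)
        marker_or = adj.loc[adj["term"] == "marker_high", "or"].iloc[0]
        assert marker_or == pytest.approx(uni["or"], rel=0.10)

    def test_perfect_separation_raises(self):
        high = np.array([0] * 20 + [1] * 20)
        y = high.copy()
        with pytest.raises(ConvergenceError):
            with pytest.warns(Warning):
                multivariable_or(_cohort_from_binary(y, high), "bcr", high)


class TestAUC:
    def test_perfect_separation_auc_one(self):
        res = auc_ci([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res["auc"] == 1.0

    def test_constant_scores_auc_half(self):
        res = auc_ci([5, 5, 5, 5], [0, 1, 0, 1])
        assert res["auc"] == 0.5

    def test_equals_mann_whitney_u_statistic(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=10)
        labels = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        pos, neg = scores[labels == 1], scores[labels == 0]
        u = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        res = auc_ci(scores, labels)
        assert res["auc"] == pytest.approx(u / (pos.size * neg.size))
        assert res["ci_low"] <= res["auc"] <= res["ci_high"]

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auc_ci([1, 2, 3], [1, 1, 1])


class TestMarkerEvaluation:
    def test_planted_hazard_recovered_end_to_end(self):
        cfg = SimConfig(cohort_n=594, marker_beta=0.9)
        cohort, truth = gen_cohort(cfg, seed=21)
        half = len(cohort) // 2
        train = SurvivalCohort(cohort.table.iloc[:half].reset_index(drop=True))
        test = SurvivalCohort(cohort.table.iloc[half:].reset_index(drop=True))
        report = evaluate_marker(train, test, covariates=["pT3plus", "LNI"])
        assert report["bcr"]["logrank"]["p"] < 0.05
        assert report["bcr"]["univariable"]["or"] > 1.0
        assert report["bcr"]["auc"]["auc"] > 0.55
        assert "multivariable" in report["bcr"]
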