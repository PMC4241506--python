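"""Wilcoxon DE, BH correction, nomination ranking and small utilities."""
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from erlnc.catalog import AnnotatedLncRNA
from erlnc.diffexpr import (ExpressionMatrix, NominationCriteria, bh_adjust,
                            median_expression_percentile, nominate_candidates,
                            pairwise_de, qpcr_fold_change, rank_peaks,
                            wilcoxon_rank_sum)
from erlnc.intervals import GeneModel, GenomicInterval, PeakInterval


def exact_wilcoxon_oracle(x, y):
    """Two-sided rank-sum p by full enumeration of rank assignments.

    Tie-free samples only: every C(n+m, n) assignment of pooled ranks to x
    is equally likely under H0; p = min(1, 2 * min(P(W <= w), P(W >= w))).
    """
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle needs tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in x)
    n = len(x)
    total = le = ge = 0
    for combo in itertools.combinations(range(1, len(pooled) + 1), n):
        w = sum(combo)
        total += 1
        le += w <= w_obs
        ge += w >= w_obs
    return min(1.0, 2 * min(le, ge) / total)


class TestWilcoxon:
    def test_textbook_separation_example(self):
        stat, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)
        assert stat == 6.0  # minimal possible rank sum for n=3

    def test_identical_multisets_give_p_one(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_two_sided_symmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=8), rng.normal(1.0, size=6)
        assert wilcoxon_rank_sum(x, y)[1] == pytest.approx(wilcoxon_rank_sum(y, x)[1])

    def test_matches_enumeration_oracle_small_samples(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            nx, ny = rng.integers(1, 6, size=2)
            vals = rng.choice(10_000, size=nx + ny, replace=False).tolist()
            x, y = vals[:nx], vals[nx:]
            _, p = wilcoxon_rank_sum(x, y, method="exact")
            assert p == pytest.approx(exact_wilcoxon_oracle(x, y), abs=1e-12)

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_normal_method_close_to_exact_at_moderate_n(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=15).tolist()
        y = rng.normal(0.2, size=15).tolist()
        _, p_exact = wilcoxon_rank_sum(x, y, method="exact")
        _, p_norm = wilcoxon_rank_sum(x, y, method="normal")
        assert p_norm == pytest.approx(p_exact, abs=0.02)


class TestBH:
    def test_hand_worked_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_equal_p_unchanged(self):
        assert np.allclose(bh_adjust([0.2] * 7), 0.2)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(max_examples=300, derandomize=True)
    def test_monotone_and_dominating(self, ps):
        q = bh_adjust(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)


def _matrix(values, groups=("a", "a", "a", "b", "b", "b")):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    samples = [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix([f"f{i}" for i in range(values.shape[0])], samples,
                            values, dict(zip(samples, groups)))


class TestPairwiseDE:
    def test_constant_feature_is_null(self):
        m = _matrix([[5.0] * 6, [1, 2, 3, 9, 10, 11]])
        (r0, r1) = pairwise_de(m, [("a", "b")])
        assert r0.p_raw == 1.0 and r0.direction == "none"
        assert r1.direction == "up" and r1.p_raw == pytest.approx(0.1)

    def test_bh_within_contrast(self):
        m = _matrix(np.arange(24, dtype=float).reshape(4, 6))
        res = pairwise_de(m, [("a", "b")])
        ps = [r.p_raw for r in res]
        assert np.allclose([r.q_bh for r in res], bh_adjust(ps))

    def test_missing_group_raises(self):
        with pytest.raises(ValueError):
            pairwise_de(_matrix([[1, 2, 3, 4, 5, 6]]), [("a", "zzz")])

    def test_planted_recovery(self):
        # 500 null + 50 planted 4-fold features, n=20/20, lognormal sigma=0.5
        rng = np.random.default_rng(2024)
        n_null, n_planted, n = 500, 50, 20
        base = np.exp(rng.normal(1.0, 1.0, size=(n_null + n_planted, 1)))
        vals = base * np.exp(0.5 * rng.standard_normal((n_null + n_planted, 2 * n)))
        vals[n_null:, n:] *= 4.0
        groups = ["a"] * n + ["b"] * n
        m = _matrix(vals, groups)
        res = pairwise_de(m, [("a", "b")])
        sig_up = {r.feature_id for r in res if r.q_bh <= 0.01 and r.direction == "up"}
        planted = {f"f{i}" for i in range(n_null, n_null + n_planted)}
        recall = len(sig_up & planted) / n_planted
        assert recall >= 0.9

    def test_label_permutation_type_i_control(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(1000, 20))
        m = _matrix(vals, ["a"] * 10 + ["b"] * 10)
        res = pairwise_de(m, [("a", "b")])
        frac = np.mean([r.p_raw <= 0.05 for r in res])
        assert 0.03 <= frac <= 0.07


def _annotated(gid, **flags):
    defaults = dict(intergenic=True, er_promoter=True, ar_promoter=False,
                    ere_full=None, ere_half=None, h3k4me3_promoter=False,
                    h3k36me3_body=False, h3k9me3=False, h3k27me3=False)
    defaults.update(flags)
    gene = GeneModel(gid, "lncRNA", GenomicInterval("chr1", 0, 1000))
    return AnnotatedLncRNA(gene=gene, **defaults)


def _de(fid, q, direction="up", log2fc=2.0, contrast=("benign", "PCa")):
    from erlnc.diffexpr import DEResult
    return DEResult(feature_id=fid, contrast=contrast, statistic=0.0,
                    p_raw=q / 2, q_bh=q, direction=direction, log2fc=log2fc)


class TestNominate:
    def test_manual_filter_and_sort_oracle(self):
        annotated = [_annotated("a"), _annotated("b"),
                     _annotated("c", intergenic=False),
                     _annotated("d", er_promoter=False), _annotated("e")]
        de = [_de("a", 0.005, log2fc=1.0), _de("b", 0.001),
              _de("c", 0.001), _de("d", 0.001),
              _de("e", 0.005, log2fc=3.0)]
        out = nominate_candidates(annotated, de)
        # c fails intergenic, d fails binding; e beats a on |log2FC| at equal q
        assert list(out["feature_id"]) == ["b", "e", "a"]

    def test_no_passing_feature_gives_empty_table(self):
        out = nominate_candidates([_annotated("a")], [_de("a", 0.5)])
        assert len(out) == 0

    def test_equal_q_and_fold_tie_breaks_by_id(self):
        annotated = [_annotated("zz"), _annotated("aa")]
        de = [_de("zz", 0.001), _de("aa", 0.001)]
        out = nominate_candidates(annotated, de)
        assert list(out["feature_id"]) == ["aa", "zz"]

    def test_input_order_invariance(self):
        annotated = [_annotated(g) for g in "abcde"]
        de = [_de(g, q) for g, q in zip("abcde", [0.004, 0.002, 0.009, 0.001, 0.003])]
        fwd = nominate_candidates(annotated, de)
        rev = nominate_candidates(annotated[::-1], de[::-1])
        assert list(fwd["feature_id"]) == list(rev["feature_id"])

    def test_missing_contrast_raises(self):
        with pytest.raises(ValueError):
            nominate_candidates([_annotated("a")],
                                [_de("a", 0.001, contrast=("x", "y"))])

    def test_histone_evidence_filters(self):
        annotated = [_annotated("k4", h3k4me3_promoter=True),
                     _annotated("k36", h3k36me3_body=True),
                     _annotated("both", h3k4me3_promoter=True, h3k36me3_body=True),
                     _annotated("none")]
        de = [_de(g, 0.001) for g in ("k4", "k36", "both", "none")]
        either = nominate_candidates(annotated, de,
                                     NominationCriteria(histone_evidence="k4_or_k36"))
        assert set(either["feature_id"]) == {"k4", "k36", "both"}
        both = nominate_candidates(annotated, de,
                                   NominationCriteria(histone_evidence="k4_and_k36"))
        assert set(both["feature_id"]) == {"both"}


class TestRankPeaks:
    PEAKS = [PeakInterval("c", 0, 10, name="weak", score=0.5),
             PeakInterval("c", 0, 10, name="strong", score=1e-9),
             PeakInterval("c", 0, 10, name="mid", score=1e-4)]

    def test_pvalue_semantics_ascending(self):
        assert [p.name for p in rank_peaks(self.PEAKS)] == ["strong", "mid", "weak"]

    def test_signal_semantics_flips_order(self):
        assert [p.name for p in rank_peaks(self.PEAKS, "signal")] == \
            ["weak", "mid", "strong"]

    def test_ties_are_stable(self):
        peaks = [PeakInterval("c", 0, 10, name=f"p{i}", score=0.5) for i in range(4)]
        assert [p.name for p in rank_peaks(peaks)] == ["p0", "p1", "p2", "p3"]

    def test_missing_score_raises(self):
        with pytest.raises(ValueError):
            rank_peaks([PeakInterval("c", 0, 10)])


class TestSmallUtilities:
    @pytest.mark.parametrize("ddct,expected", [(0.0, 1.0), (-1.0, 2.0)])
    def test_qpcr_fold_simple(self, ddct, expected):
        assert qpcr_fold_change(10 + ddct, 10, 5, 5) == pytest.approx(expected)

    def test_qpcr_fold_tenth(self):
        fold = qpcr_fold_change(13.3219, 10, 5, 5)
        assert fold == pytest.approx(0.1, abs=1e-3)

    def test_percentile_single_feature(self):
        m = _matrix([[1, 2, 3, 4, 5, 6]])
        assert median_expression_percentile(m, "f0") == 100.0

    def test_percentile_second_highest_of_100(self):
        vals = np.arange(100, dtype=float)[:, None] * np.ones((1, 6))
        m = _matrix(vals)
        assert median_expression_percentile(m, "f98") == 99.0

    def test_percentile_lowest_counts_itself(self):
        vals = np.arange(100, dtype=float)[:, None] * np.ones((1, 6))
        m = _matrix(vals)
        assert median_expression_percentile(m, "f0") == 1.0

    def test_percentile_missing_feature_raises(self):
        with pytest.raises(KeyError):
            median_expression_percentile(_matrix([[1, 2, 3, 4, 5, 6]]), "nope")
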