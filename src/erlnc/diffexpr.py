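"""Pairwise Wilcoxon differential expression, BH correction and nomination.

Expression is compared between tissue groups (benign / PCa / NEPC by
default) with the two-sample Wilcoxon rank-sum test, corrected within each
contrast by Benjamini-Hochberg.  Candidates are nominated by combining DE
significance and direction with the binding/annotation evidence flags, and
ranked deterministically (q ascending, |log2 fold change| descending, id).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .catalog import AnnotatedLncRNA
from .intervals import PeakInterval

__all__ = [
    "ExpressionMatrix",
    "DEResult",
    "NominationCriteria",
    "wilcoxon_rank_sum",
    "bh_adjust",
    "pairwise_de",
    "nominate_candidates",
    "rank_peaks",
    "qpcr_fold_change",
    "median_expression_percentile",
]

#: Pseudocount (expression units) used for log2 fold changes on RPKM-like
#: values that may be zero.
LOG2FC_EPS = 0.1


@dataclass
class ExpressionMatrix:
    """Features x samples expression values plus a sample-group factor."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    group: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        missing = [s for s in self.sample_ids if s not in self.group]
        if missing:
            raise ValueError(f"samples without a group: {missing[:5]}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite expression values")

    def group_columns(self, group_name: str) -> np.ndarray:
        cols = [i for i, s in enumerate(self.sample_ids) if self.group[s] == group_name]
        if not cols:
            raise ValueError(f"group {group_name!r} has no samples")
        return self.values[:, cols]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_tsv(cls, matrix_path, groups_path) -> "ExpressionMatrix":
        df = pd.read_csv(matrix_path, sep="\t", index_col=0)
        groups = pd.read_csv(groups_path, sep="\t", index_col=0).iloc[:, 0].to_dict()
        return cls(list(df.index), list(df.columns), df.to_numpy(), groups)


@dataclass
class DEResult:
    """One feature x contrast differential-expression record."""

    feature_id: str
    contrast: tuple[str, str]
    statistic: float
    p_raw: float
    q_bh: float
    direction: str  # up / down / none, by sign of median(b) - median(a)
    log2fc: float = float("nan")


@dataclass
class NominationCriteria:
    """Evidence filters applied on top of DE significance (Fig-style funnel)."""

    require_intergenic: bool = True
    require_er_promoter: bool = True
    histone_evidence: str = "none"  # none | k4_or_k36 | k4_and_k36
    fdr_max: float = 0.01
    contrast: tuple[str, str] = ("benign", "PCa")
    direction: str = "up"

    def __post_init__(self) -> None:
        if not (0 < self.fdr_max < 1):
            raise ValueError("fdr_max must be in (0, 1)")
        if self.histone_evidence not in ("none", "k4_or_k36", "k4_and_k36"):
            raise ValueError(f"unknown histone_evidence {self.histone_evidence!r}")


def wilcoxon_rank_sum(x, y, alternative: str = "two_sided",
                      method: str = "auto") -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum test.

    Returns ``(W, p)`` where W is the rank-sum of ``x`` (midranks for ties).
    ``method='auto'`` uses exact enumeration when ``len(x)*len(y) <= 400``
    and the pooled sample is tie-free, otherwise the normal approximation
    with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}.get(alternative)
    if alt is None:
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if method == "auto":
        method = "exact" if (x.size * y.size <= 400 and not has_ties) else "normal"
    if method not in ("exact", "normal"):
        raise ValueError(f"unknown method {method!r}")
    scipy_method = "exact" if method == "exact" else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alt, method=scipy_method,
                             use_continuity=(method == "normal"))
    # W = U_x + n_x (n_x + 1) / 2
    statistic = float(res.statistic + x.size * (x.size + 1) / 2)
    return statistic, float(min(res.pvalue, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving in input indexing."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _median_log2fc(med_a: np.ndarray, med_b: np.ndarray, eps: float = LOG2FC_EPS) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.log2((med_b + eps) / (med_a + eps))


def pairwise_de(matrix: ExpressionMatrix,
                contrasts: Sequence[tuple[str, str]],
                fdr_max: float = 0.01) -> list[DEResult]:
    """Per-contrast Wilcoxon DE over all features, BH within each contrast.

    Direction is the sign of ``median(b) - median(a)``.  The Wilcoxon method
    follows the same auto rule as :func:`wilcoxon_rank_sum`, vectorized
    across features.
    """
    results: list[DEResult] = []
    for (ga, gb) in contrasts:
        a = matrix.group_columns(ga)
        b = matrix.group_columns(gb)
        if a.shape[1] < 2 or b.shape[1] < 2:
            raise ValueError(f"contrast ({ga}, {gb}) needs >= 2 samples per group")
        pooled = np.concatenate([a, b], axis=1)
        tie_free = np.array([np.unique(row).size == row.size for row in pooled])
        exact_ok = tie_free & (a.shape[1] * b.shape[1] <= 400)
        p_raw = np.empty(pooled.shape[0])
        u_stat = np.empty(pooled.shape[0])
        for mask, scipy_method in ((exact_ok, "exact"), (~exact_ok, "asymptotic")):
            if not mask.any():
                continue
            res = stats.mannwhitneyu(a[mask], b[mask], alternative="two-sided",
                                     axis=1, method=scipy_method,
                                     use_continuity=(scipy_method == "asymptotic"))
            p_raw[mask] = np.asarray(res.pvalue, dtype=float)
            u_stat[mask] = np.asarray(res.statistic, dtype=float)
        p_raw = np.minimum(p_raw, 1.0)
        stat = u_stat + a.shape[1] * (a.shape[1] + 1) / 2
        # constant features: identical multisets carry no evidence
        const = np.array([np.unique(row).size == 1 for row in pooled])
        p_raw[const] = 1.0
        q = bh_adjust(p_raw)
        med_a = np.median(a, axis=1)
        med_b = np.median(b, axis=1)
        log2fc = _median_log2fc(med_a, med_b)
        diff = med_b - med_a
        for i, fid in enumerate(matrix.feature_ids):
            direction = "none" if diff[i] == 0 else ("up" if diff[i] > 0 else "down")
            results.append(DEResult(feature_id=fid, contrast=(ga, gb),
                                    statistic=float(stat[i]), p_raw=float(p_raw[i]),
                                    q_bh=float(q[i]), direction=direction,
                                    log2fc=float(log2fc[i])))
    return results


def nominate_candidates(annotated: Sequence[AnnotatedLncRNA],
                        de: Sequence[DEResult],
                        criteria: NominationCriteria = NominationCriteria()) -> pd.DataFrame:
    """Filter and rank candidate receptor-regulated lncRNAs.

    Keeps features passing the evidence flags, q <= fdr_max and the required
    direction in the criteria's contrast; sorts by (q asc, |log2FC| desc,
    feature_id asc).  Returns a table with per-candidate evidence columns.
    """
    de_for = {r.feature_id: r for r in de if r.contrast == tuple(criteria.contrast)}
    if not de_for:
        raise ValueError(f"no DE results for contrast {criteria.contrast}")
    rows = []
    for a in annotated:
        r = de_for.get(a.gene.gene_id)
        if r is None:
            continue
        if criteria.require_intergenic and not a.intergenic:
            continue
        if criteria.require_er_promoter and not a.er_promoter:
            continue
        if criteria.histone_evidence == "k4_or_k36" and not (a.h3k4me3_promoter or a.h3k36me3_body):
            continue
        if criteria.histone_evidence == "k4_and_k36" and not (a.h3k4me3_promoter and a.h3k36me3_body):
            continue
        if r.q_bh > criteria.fdr_max or r.direction != criteria.direction:
            continue
        rows.append({
            "feature_id": a.gene.gene_id, "q_bh": r.q_bh, "p_raw": r.p_raw,
            "log2fc": r.log2fc, "direction": r.direction,
            "intergenic": a.intergenic, "er_promoter": a.er_promoter,
            "ar_promoter": a.ar_promoter, "ere_full": a.ere_full,
            "ere_half": a.ere_half, "h3k4me3_promoter": a.h3k4me3_promoter,
            "h3k36me3_body": a.h3k36me3_body,
            "h3k9me3": a.h3k9me3, "h3k27me3": a.h3k27me3,
        })
    df = pd.DataFrame(rows, columns=[
        "feature_id", "q_bh", "p_raw", "log2fc", "direction", "intergenic",
        "er_promoter", "ar_promoter", "ere_full", "ere_half",
        "h3k4me3_promoter", "h3k36me3_body", "h3k9me3", "h3k27me3"])
    if df.empty:
        return df
    df["_absfc"] = df["log2fc"].abs()
    df = df.sort_values(["q_bh", "_absfc", "feature_id"],
                        ascending=[True, False, True], kind="mergesort")
    return df.drop(columns="_absfc").reset_index(drop=True)


def rank_peaks(peaks: Sequence[PeakInterval],
               score_semantics: str = "pvalue") -> list[PeakInterval]:
    """Order peaks by strength: ascending p-value or descending signal.

    Stable for ties (input order preserved).
    """
    if score_semantics not in ("pvalue", "signal"):
        raise ValueError(f"unknown score_semantics {score_semantics!r}")
    if any(p.score is None for p in peaks):
        raise ValueError("all peaks need scores for ranking")
    reverse = score_semantics == "signal"
    return sorted(peaks, key=lambda p: -p.score if reverse else p.score)


def qpcr_fold_change(ct_target_s: float, ct_ref_s: float,
                     ct_target_c: float, ct_ref_c: float) -> float:
    """Relative expression by the ddCt method: 2^-((dCt_sample) - (dCt_control))."""
    ddct = (ct_target_s - ct_ref_s) - (ct_target_c - ct_ref_c)
    return float(2.0 ** (-ddct))


def median_expression_percentile(matrix: ExpressionMatrix, feature_id: str) -> float:
    """Percentile rank (0-100] of a feature's median among all feature medians.

    Uses the <= convention, so the feature's own median counts and the
    lowest-expressed feature of n sits at 100/n.
    """
    if feature_id not in matrix.feature_ids:
        raise KeyError(feature_id)
    medians = np.median(matrix.values, axis=1)
    target = medians[matrix.feature_ids.index(feature_id)]
    return float(100.0 * np.sum(medians <= target) / medians.size)
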