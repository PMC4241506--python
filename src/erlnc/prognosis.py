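"""Biomarker prognosis workflow: PSR selection, cut-points, KM, ORs, AUC.

The workflow mirrors a two-cohort design: the expression cut-point that
dichotomizes the marker is learned on a training set by maximizing
sensitivity x specificity for each endpoint, then applied to a test set
where Kaplan-Meier curves and the log-rank test compare marker-high vs
marker-low survival.  Endpoints are treated as binary for odds ratios and
AUC, and as time-to-event for KM/log-rank.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "SurvivalCohort",
    "CutpointResult",
    "KMCurve",
    "ConvergenceError",
    "COVARIATE_NAMES",
    "ENDPOINTS",
    "select_psr",
    "optimal_cutpoint",
    "km_estimate",
    "logrank_test",
    "univariable_or",
    "or_from_table",
    "multivariable_or",
    "auc_ci",
    "evaluate_marker",
]

COVARIATE_NAMES = ("pT3plus", "LNI", "SMS", "SVI", "ECE", "pPSA",
                   "adjuvant_radiation", "adjuvant_hormone")
#: endpoint -> binary outcome column
ENDPOINTS = {"bcr": "event_bcr", "met": "event_met", "pcsm": "event_pcsm",
             "gs7": "gs_gt7"}


class ConvergenceError(RuntimeError):
    """Logistic fit failed to converge (for example, perfect separation)."""


@dataclass
class SurvivalCohort:
    """Per-patient marker expression, endpoint times/events and covariates."""

    table: pd.DataFrame

    REQUIRED = ("id", "marker_expression", "time_bcr", "event_bcr",
                "time_met", "event_met", "event_pcsm", "gs_gt7")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        for col in ("time_bcr", "time_met"):
            if (self.table[col] < 0).any():
                raise ValueError(f"negative times in {col}")
        for col in ("event_bcr", "event_met", "event_pcsm", "gs_gt7"):
            if not self.table[col].isin([0, 1]).all():
                raise ValueError(f"{col} must be binary 0/1")
        extra = set(self.table.columns) - set(self.REQUIRED) - set(COVARIATE_NAMES)
        if extra:
            raise ValueError(f"unknown covariate columns: {sorted(extra)}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def covariates(self) -> list[str]:
        return [c for c in COVARIATE_NAMES if c in self.table.columns]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SurvivalCohort":
        return cls(pd.read_csv(path, sep="\t"))


def select_psr(probe_matrix: pd.DataFrame, probe_to_psr: Mapping[str, str]) -> str:
    """Pick the probe selection region with minimal technical variance.

    Technical variance of a PSR is the median over samples of the variance
    among its probes' values within each sample (sample variance when the
    PSR has >= 2 probes, zero for a single probe).  Ties break by PSR id.
    """
    if probe_matrix.empty:
        raise ValueError("empty probe matrix")
    unknown = set(probe_matrix.index) - set(probe_to_psr)
    if unknown:
        raise ValueError(f"probes without a PSR: {sorted(unknown)[:5]}")
    scores: dict[str, float] = {}
    psr_groups: dict[str, list[str]] = {}
    for probe, psr in probe_to_psr.items():
        if probe in probe_matrix.index:
            psr_groups.setdefault(psr, []).append(probe)
    for psr, probes in psr_groups.items():
        sub = probe_matrix.loc[probes].to_numpy()
        ddof = 1 if sub.shape[0] >= 2 else 0
        per_sample_var = sub.var(axis=0, ddof=ddof) if sub.shape[0] >= 2 \
            else np.zeros(sub.shape[1])
        scores[psr] = float(np.median(per_sample_var))
    return min(scores, key=lambda k: (scores[k], k))


@dataclass
class CutpointResult:
    cut: float
    sensitivity: float
    specificity: float
    product: float
    endpoint: str = ""


def optimal_cutpoint(scores, labels, endpoint: str = "") -> CutpointResult:
    """Cut maximizing sensitivity x specificity over all candidate cuts.

    Candidates are the midpoints of consecutive sorted unique scores;
    ``score >= cut`` classifies as high/positive.  Ties on the product go to
    the lowest cut.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.size != labels.size or scores.size == 0:
        raise ValueError("scores and labels must be equal-length, non-empty")
    pos = labels == 1
    if pos.all() or (~pos).all():
        raise ValueError("both classes must be present")
    uniq = np.unique(scores)
    if uniq.size < 2:
        raise ValueError("all scores identical: no candidate cut exists")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best: CutpointResult | None = None
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    for cut in candidates:  # ascending, so ties keep the lowest cut
        pred = scores >= cut
        sens = float(np.sum(pred & pos)) / n_pos
        spec = float(np.sum(~pred & ~pos)) / n_neg
        prod = sens * spec
        if best is None or prod > best.product:
            best = CutpointResult(cut=float(cut), sensitivity=sens,
                                  specificity=spec, product=prod, endpoint=endpoint)
    return best


@dataclass
class KMCurve:
    """Product-limit survival estimate as a step function."""

    event_times: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray
    censor_times: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.event_times, "at_risk": self.at_risk,
                             "survival": self.survival})


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier estimate; censored subjects at an event time stay at risk."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("no observations")
    if np.any(times < 0):
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    event_times = ev.index.to_numpy(dtype=float)
    at_risk = ev["at_risk"].to_numpy(dtype=float)
    survival = np.asarray([kmf.predict(t) for t in event_times], dtype=float)
    censor_times = table.index[table["censored"] > 0].to_numpy(dtype=float)
    return KMCurve(event_times=event_times, at_risk=at_risk, survival=survival,
                   censor_times=censor_times)


def logrank_test(group_a: tuple, group_b: tuple) -> dict:
    """Two-group log-rank test; returns chi-square statistic and p (chi2, 1 df)."""
    (ta, ea), (tb, eb) = group_a, group_b
    ta, ea = np.asarray(ta, dtype=float), np.asarray(ea, dtype=int)
    tb, eb = np.asarray(tb, dtype=float), np.asarray(eb, dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no events in either group")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return {"chi_square": float(res.test_statistic), "p": float(res.p_value)}


def or_from_table(a: float, b: float, c: float, d: float) -> dict:
    """OR with 95% Wald CI and p from a 2x2 table (a,b;c,d).

    Haldane 0.5 correction is applied when any cell is zero.  An empty
    margin makes the OR undefined and raises.
    """
    if min(a + b, c + d, a + c, b + d) == 0:
        raise ValueError("empty margin in 2x2 table")
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = np.log(or_)
    z = log_or / se
    p = 2 * stats.norm.sf(abs(z))
    return {"or": float(or_), "ci_low": float(np.exp(log_or - 1.96 * se)),
            "ci_high": float(np.exp(log_or + 1.96 * se)), "p": float(p)}


def univariable_or(exposure, outcome) -> dict:
    """OR of a binary exposure for a binary outcome from per-subject vectors."""
    exposure = np.asarray(exposure, dtype=int)
    outcome = np.asarray(outcome, dtype=int)
    a = int(np.sum((exposure == 1) & (outcome == 1)))
    b = int(np.sum((exposure == 1) & (outcome == 0)))
    c = int(np.sum((exposure == 0) & (outcome == 1)))
    d = int(np.sum((exposure == 0) & (outcome == 0)))
    return or_from_table(a, b, c, d)


def multivariable_or(cohort: SurvivalCohort, endpoint: str, marker_high,
                     covariates: Sequence[str] = (),
                     maxiter: int = 100, tol: float = 1e-8) -> pd.DataFrame:
    """Adjusted odds ratios from a maximum-likelihood logistic model.

    One row per term (marker first, then covariates) with OR = exp(coef) and
    Wald 95% CIs.  Perfect separation or non-convergence raises
    :class:`ConvergenceError` rather than returning silent output.
    """
    col = ENDPOINTS.get(endpoint)
    if col is None:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    y = cohort.table[col].to_numpy(dtype=float)
    marker_high = np.asarray(marker_high, dtype=float)
    X = pd.DataFrame({"marker_high": marker_high})
    for cov in covariates:
        if cov not in cohort.table.columns:
            raise ValueError(f"covariate {cov!r} not in cohort")
        X[cov] = cohort.table[cov].to_numpy(dtype=float)
    n_min = 10 * (len(covariates) + 2)
    if len(y) <= n_min:
        import warnings
        warnings.warn(f"n={len(y)} is small for {len(covariates) + 1} terms",
                      stacklevel=2)
    X = sm.add_constant(X, prepend=True)
    try:
        fit = sm.Logit(y, X).fit(method="newton", maxiter=maxiter, tol=tol, disp=0)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise ConvergenceError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise ConvergenceError("logistic fit did not converge")
    if np.any(np.abs(fit.params.to_numpy()[1:]) > 15):
        raise ConvergenceError("diverging coefficients (likely separation)")
    params = fit.params.drop("const")
    ci = fit.conf_int(alpha=0.05).drop(index="const")
    pvals = fit.pvalues.drop("const")
    return pd.DataFrame({
        "term": params.index,
        "or": np.exp(params.to_numpy()),
        "ci_low": np.exp(ci[0].to_numpy()),
        "ci_high": np.exp(ci[1].to_numpy()),
        "p": pvals.to_numpy(),
    }).reset_index(drop=True)


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values (ties get half credit)."""
    v10 = np.empty(pos.size)
    for i, s in enumerate(pos):
        v10[i] = (np.sum(neg < s) + 0.5 * np.sum(neg == s)) / neg.size
    v01 = np.empty(neg.size)
    for j, s in enumerate(neg):
        v01[j] = (np.sum(pos > s) + 0.5 * np.sum(pos == s)) / pos.size
    return v10, v01


def auc_ci(scores, labels) -> dict:
    """AUC by the Mann-Whitney rank statistic with a DeLong 95% CI."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    v10, v01 = _placements(pos, neg)
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if pos.size > 1 else 0.0
    s01 = v01.var(ddof=1) if neg.size > 1 else 0.0
    se = np.sqrt(s10 / pos.size + s01 / neg.size)
    return {"auc": auc, "ci_low": float(max(0.0, auc - 1.96 * se)),
            "ci_high": float(min(1.0, auc + 1.96 * se))}


def evaluate_marker(train: SurvivalCohort, test: SurvivalCohort,
                    endpoints: Sequence[str] = ("bcr", "met", "pcsm", "gs7"),
                    covariates: Sequence[str] | None = None) -> dict:
    """Full marker evaluation: cut-points on train, KM/log-rank/OR/AUC on test.

    Returns a nested dict keyed by endpoint with the learned cut-point,
    log-rank result (time-to-event endpoints only), univariable OR and AUC,
    plus a multivariable OR table when covariates are supplied.
    """
    out: dict = {}
    for ep in endpoints:
        col = ENDPOINTS[ep]
        cp = optimal_cutpoint(train.table["marker_expression"],
                              train.table[col], endpoint=ep)
        high = (test.table["marker_expression"] >= cp.cut).to_numpy().astype(int)
        entry: dict = {"cutpoint": cp, "n_high": int(high.sum()),
                       "n_low": int((1 - high).sum())}
        if ep in ("bcr", "met"):
            t = test.table[f"time_{ep}"].to_numpy()
            e = test.table[col].to_numpy()
            entry["logrank"] = logrank_test((t[high == 1], e[high == 1]),
                                            (t[high == 0], e[high == 0]))
            entry["km_high"] = km_estimate(t[high == 1], e[high == 1])
            entry["km_low"] = km_estimate(t[high == 0], e[high == 0])
        entry["univariable"] = univariable_or(high, test.table[col])
        entry["auc"] = auc_ci(test.table["marker_expression"], test.table[col])
        if covariates:
            try:
                entry["multivariable"] = multivariable_or(test, ep, high, covariates)
            except ConvergenceError as exc:
                entry["multivariable_error"] = str(exc)
        out[ep] = entry
    return out
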