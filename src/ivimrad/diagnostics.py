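"""Benign/malignant diagnostic evaluation of radiomic metrics.

Per metric and per fitting method: a site-adjusted logistic regression
(site-specific intercept and slope, i.e. the full site × metric
interaction), apparent and leave-one-patient-out (LOU) cross-validated
AUC with DeLong standard errors, paired DeLong tests between methods, and
cross-method AUC mean/CV rankings.

The metric is z-scored over the pooled sample before fitting; LOU folds
reuse the full-sample standardization constants (they leak no label
information). Complete separation is detected by a diverging slope and
handled with a weak ridge (1e-4), to which the AUC is rank-invariant.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .agreement import average_and_cv

__all__ = [
    "LogisticModelFit", "AUCResult", "fit_site_adjusted_logistic",
    "predict_prob", "auc_delong", "delong_paired_test", "lou_cv_auc",
    "diagnostic_study",
]

_MAX_IRLS = 100
_LL_TOL = 1e-8
_RIDGE = 1e-4
_BETA_DIVERGED = 10.0   # |slope| of a z-scored metric this large means separation


@dataclass
class LogisticModelFit:
    """Site-adjusted fit: per-site intercept alpha_s and slope beta_s."""

    sites: list[str]
    alpha: dict[str, float]
    beta: dict[str, float]
    x_mean: float
    x_sd: float
    shared_slope: bool
    converged: bool
    separation_flag: bool
    cov: np.ndarray | None = None     # inverse observed information


@dataclass
class AUCResult:
    auc: float
    se: float
    kind: str                          # "apparent" | "lou"
    n_flagged_folds: int = 0


def _design(x: np.ndarray, site_idx: np.ndarray, n_sites: int,
            shared_slope: bool) -> np.ndarray:
    onehot = np.eye(n_sites)[site_idx]
    if shared_slope:
        return np.column_stack([onehot, x])
    return np.column_stack([onehot, onehot * x[:, None]])


def _irls(X: np.ndarray, y: np.ndarray, ridge: float,
          beta0: np.ndarray | None = None):
    """Newton/IRLS maximum likelihood with optional ridge penalty."""
    p_dim = X.shape[1]
    beta = np.zeros(p_dim) if beta0 is None else beta0.copy()
    ll_old = -np.inf
    converged = False
    for _ in range(_MAX_IRLS):
        eta = np.clip(X @ beta, -35, 35)
        mu = expit(eta)
        ll = float(y @ eta - np.sum(np.log1p(np.exp(eta)))) \
            - 0.5 * ridge * float(beta @ beta)
        w = mu * (1 - mu)
        H = X.T * w @ X + ridge * np.eye(p_dim) + 1e-12 * np.eye(p_dim)
        g = X.T @ (y - mu) - ridge * beta
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        beta = beta + step
        if abs(ll - ll_old) < _LL_TOL:
            converged = True
            break
        ll_old = ll
    return beta, converged, H


def fit_site_adjusted_logistic(scores, site_tags, labels,
                               shared_slope: bool = False,
                               standardize: tuple[float, float] | None = None
                               ) -> LogisticModelFit:
    """Maximum-likelihood logit P(malignant) = alpha_site + beta_site * x.

    ``standardize`` optionally supplies (mean, sd) z-scoring constants;
    by default they are computed from the pooled input sample.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    tags = np.asarray(site_tags)
    if len(np.unique(y)) < 2:
        raise ValueError("need both benign (0) and malignant (1) labels")
    if standardize is None:
        x_mean, x_sd = float(x.mean()), float(x.std(ddof=0))
    else:
        x_mean, x_sd = standardize
    x_sd = x_sd if x_sd > 0 else 1.0
    z = (x - x_mean) / x_sd
    sites = sorted(np.unique(tags).tolist())
    site_idx = np.searchsorted(sites, tags)
    X = _design(z, site_idx, len(sites), shared_slope)

    beta, converged, H = _irls(X, y, ridge=0.0)
    separation = bool(np.max(np.abs(beta)) > _BETA_DIVERGED or
                      not np.all(np.isfinite(beta)) or not converged)
    if separation:
        beta, converged, H = _irls(X, y, ridge=_RIDGE)
    k = len(sites)
    alpha = dict(zip(sites, beta[:k]))
    if shared_slope:
        slope = dict.fromkeys(sites, float(beta[k]))
    else:
        slope = dict(zip(sites, beta[k:]))
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = None
    return LogisticModelFit(sites, alpha, slope, x_mean, x_sd, shared_slope,
                            bool(converged), separation, cov)


def predict_prob(model: LogisticModelFit, scores, site_tags) -> np.ndarray:
    """Inverse-logit of the linear predictor for new (score, site) pairs."""
    x = np.asarray(scores, dtype=float)
    tags = np.asarray(site_tags)
    unseen = sorted(set(tags.tolist()) - set(model.sites))
    if unseen:
        raise ValueError(f"unseen site tag(s) {unseen}; model knows {model.sites}")
    z = (x - model.x_mean) / model.x_sd
    eta = np.array([model.alpha[t] for t in tags]) \
        + np.array([model.beta[t] for t in tags]) * z
    return expit(eta)


# ---------------------------------------------------------------------------
# DeLong machinery

def _midrank(v: np.ndarray) -> np.ndarray:
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(len(v))
    i = 0
    sv = v[order]
    while i < len(v):
        j = i
        while j < len(v) and sv[j] == sv[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    return ranks


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """AUC and the per-subject structural components V10, V01."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("need both classes present")
    allv = np.concatenate([pos, neg])
    r_all = _midrank(allv)
    r_pos = _midrank(pos)
    r_neg = _midrank(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[:m] - r_pos) / n              # per positive subject
    v01 = 1.0 - (r_all[m:] - r_neg) / m        # per negative subject
    return float(auc), v10, v01


def auc_delong(scores, labels, kind: str = "apparent") -> AUCResult:
    """Mann-Whitney AUC (ties at 1/2) with DeLong's standard error."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    auc, v10, v01 = _delong_components(scores, labels)
    s10 = v10.var(ddof=1) if len(v10) > 1 else 0.0
    s01 = v01.var(ddof=1) if len(v01) > 1 else 0.0
    se = float(np.sqrt(s10 / len(v10) + s01 / len(v01)))
    return AUCResult(auc=auc, se=se, kind=kind)


def delong_paired_test(scores_1, scores_2, labels) -> tuple[float, float]:
    """Two-sided z-test on the AUC difference of two score sets on the same
    patients, using the paired DeLong covariance of structural components.

    Returns (z, p); degenerate zero-variance differences give (0, 1).
    """
    labels = np.asarray(labels).astype(int)
    a1, v10_1, v01_1 = _delong_components(np.asarray(scores_1, float), labels)
    a2, v10_2, v01_2 = _delong_components(np.asarray(scores_2, float), labels)
    m, n = len(v10_1), len(v01_1)
    if m > 1:
        s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1)
    else:
        s10 = np.zeros((2, 2))
    if n > 1:
        s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1)
    else:
        s01 = np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        return 0.0, 1.0
    z = (a1 - a2) / np.sqrt(var)
    p = 2.0 * float(norm.sf(abs(z)))
    return float(z), p


# ---------------------------------------------------------------------------
# leave-one-patient-out cross-validation

def lou_cv_auc(scores, site_tags, labels, shared_slope: bool = False
               ) -> AUCResult:
    """Out-of-sample AUC: refit the site-adjusted logistic n times, each
    leaving one patient out, and score the pooled held-out probabilities.

    A fold whose training set loses a class entirely is flagged and the
    held-out prediction falls back to the training prevalence.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    tags = np.asarray(site_tags)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 patients for LOU cross-validation")
    std = (float(x.mean()), float(x.std(ddof=0)))
    probs = np.empty(n)
    flagged = 0
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        yt = y[mask]
        if yt.min() == yt.max():
            probs[i] = yt.mean()
            flagged += 1
        else:
            fit = fit_site_adjusted_logistic(x[mask], tags[mask], yt,
                                             shared_slope=shared_slope,
                                             standardize=std)
            probs[i] = predict_prob(fit, x[i:i + 1], tags[i:i + 1])[0]
        mask[i] = True
    res = auc_delong(probs, y, kind="lou")
    res.n_flagged_folds = flagged
    return res


# ---------------------------------------------------------------------------
# study driver

@dataclass
class DiagnosticSummary:
    """Per-metric diagnostic payload across methods."""

    metric_name: str
    auc: dict[str, AUCResult]          # method -> apparent
    lou: dict[str, AUCResult]          # method -> LOU
    mean_auc: float
    cv_auc_pct: float
    mean_lou_auc: float
    cv_lou_auc_pct: float
    delong_p: dict[tuple[str, str], float] = field(default_factory=dict)
    separation: dict[str, bool] = field(default_factory=dict)


def diagnostic_study(table: pd.DataFrame,
                     methods: tuple[str, ...] = ("seg_a", "seg_b", "bayes"),
                     shared_slope: bool = False) -> list[DiagnosticSummary]:
    """Apparent and LOU diagnostic performance for every metric × method.

    ``table`` is the tidy feature table (patient_id, site_tag, label,
    method_tag, metric_name, value). Returns summaries sorted by
    descending mean apparent AUC.
    """
    out: list[DiagnosticSummary] = []
    for metric, sub in table.groupby("metric_name", sort=False):
        wide = sub.pivot(index=["patient_id", "site_tag", "label"],
                         columns="method_tag", values="value")
        missing = [m for m in methods if m not in wide.columns]
        if missing:
            raise ValueError(f"feature table lacks methods {missing}")
        idx = wide.index.to_frame(index=False)
        tags = idx["site_tag"].to_numpy()
        y = (idx["label"] == "malignant").to_numpy().astype(int)
        app, lou, probs, sep = {}, {}, {}, {}
        for m in methods:
            x = wide[m].to_numpy()
            fit = fit_site_adjusted_logistic(x, tags, y, shared_slope=shared_slope)
            p = predict_prob(fit, x, tags)
            probs[m] = p
            sep[m] = fit.separation_flag
            app[m] = auc_delong(p, y, kind="apparent")
            lou[m] = lou_cv_auc(x, tags, y, shared_slope=shared_slope)
        mean_a, cv_a = average_and_cv([app[m].auc for m in methods])
        mean_l, cv_l = average_and_cv([lou[m].auc for m in methods])
        pvals = {(m1, m2): delong_paired_test(probs[m1], probs[m2], y)[1]
                 for m1, m2 in itertools.combinations(methods, 2)}
        out.append(DiagnosticSummary(metric, app, lou, mean_a, cv_a,
                                     mean_l, cv_l, pvals, sep))
    out.sort(key=lambda s: -s.mean_auc)
    return out


def summary_frames(summaries: list[DiagnosticSummary],
                   methods: tuple[str, ...] = ("seg_a", "seg_b", "bayes")):
    """Tabular views: per-method AUC table, per-metric ranking, p-values."""
    auc_rows, rank_rows, p_rows = [], [], []
    for s in summaries:
        for m in methods:
            auc_rows.append(dict(metric_name=s.metric_name, method_tag=m,
                                 auc=s.auc[m].auc, se=s.auc[m].se,
                                 lou_auc=s.lou[m].auc, lou_se=s.lou[m].se))
        rank_rows.append(dict(metric_name=s.metric_name, mean_auc=s.mean_auc,
                              cv_auc_pct=s.cv_auc_pct,
                              mean_lou_auc=s.mean_lou_auc,
                              cv_lou_auc_pct=s.cv_lou_auc_pct))
        for (m1, m2), p in s.delong_p.items():
            p_rows.append(dict(metric_name=s.metric_name, method_1=m1,
                               method_2=m2, p_value=p))
    return (pd.DataFrame(auc_rows), pd.DataFrame(rank_rows),
            pd.DataFrame(p_rows))
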