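"""Cross-software robustness statistics for radiomic metrics.

For every metric: pairwise Pearson correlations per site (never pooling
patients across sites), Bland-Altman difference summaries per pair and
site, the average correlation and its coefficient of variation over all
pair × site cells, and a three-rater agreement ICC per site.

The ICC is the two-way random-effects, absolute-agreement, single-rater
coefficient ICC(2,1):

    ICC(2,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

which penalizes a constant offset between software (absolute agreement,
not consistency).
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "pearson_r", "average_and_cv", "icc_absolute_agreement", "bland_altman",
    "PairAgreement", "AgreementSummary", "agreement_study",
]

log = logging.getLogger(__name__)


def pearson_r(x, y) -> float:
    """Product-moment correlation; NaN (flagged undefined) on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        log.warning("zero-variance input; correlation undefined")
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def average_and_cv(values) -> tuple[float, float]:
    """Mean and CV% (sample SD over mean) of a set of statistics.

    NaN entries (undefined cells) are excluded from both; the CV is NaN
    when the mean is zero.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 2:
        raise ValueError("need at least 2 defined values")
    mean = float(v.mean())
    if mean == 0:
        return mean, float("nan")
    return mean, float(100.0 * v.std(ddof=1) / mean)


def icc_absolute_agreement(matrix) -> float:
    """ICC(2,1) of an (n subjects × k raters) complete matrix."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 5 or m.shape[1] < 2:
        raise ValueError("need a complete (n >= 5) x (k >= 2) matrix")
    if np.isnan(m).any():
        raise ValueError("missing cells are not supported")
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_tot = np.sum((m - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if denom == 0:
        log.warning("singular ANOVA decomposition; ICC undefined")
        return float("nan")
    return float((ms_r - ms_e) / denom)


def bland_altman(x, y) -> dict:
    """Difference summaries for one method pair.

    Reports mean and SD (n-1) of the absolute differences, the
    within-subject CV% (SD of signed differences / sqrt(2), relative to the
    grand mean of all 2n measurements; the absolute-difference alternative
    is reported alongside), plus the classic signed bias and 95% limits of
    agreement for plotting.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples of length >= 3")
    d = x - y
    ad = np.abs(d)
    grand = float(np.concatenate([x, y]).mean())
    sd_d = float(d.std(ddof=1))
    if grand <= 0:
        log.warning("non-positive grand mean; Bland-Altman CV undefined")
        cv = cv_abs = float("nan")
    else:
        cv = 100.0 * (sd_d / np.sqrt(2.0)) / grand
        cv_abs = 100.0 * float(ad.mean()) / grand
    bias = float(d.mean())
    return dict(mean_abs_diff=float(ad.mean()), sd_abs_diff=float(ad.std(ddof=1)),
                cv_pct=float(cv), cv_abs_pct=float(cv_abs), bias=bias,
                loa_low=bias - 1.96 * sd_d, loa_high=bias + 1.96 * sd_d)


@dataclass
class PairAgreement:
    method_pair: tuple[str, str]
    site_tag: str
    metric_name: str
    r: float
    n: int
    ba: dict = field(default_factory=dict)


@dataclass
class AgreementSummary:
    metric_name: str
    mean_r: float
    cv_r_pct: float
    icc_per_site: dict[str, float]
    rank: int = 0


def agreement_study(table: pd.DataFrame,
                    methods: tuple[str, ...] = ("seg_a", "seg_b", "bayes"),
                    min_patients: int = 3):
    """Robustness statistics for every metric in a tidy feature table.

    ``table`` columns: patient_id, site_tag, label, method_tag, metric_name,
    value. Returns (summaries sorted by descending mean r, pair records).
    """
    pairs = list(itertools.combinations(methods, 2))
    summaries: list[AgreementSummary] = []
    records: list[PairAgreement] = []
    for metric, sub in table.groupby("metric_name", sort=False):
        wide_all = sub.pivot(index=["patient_id", "site_tag"],
                             columns="method_tag", values="value")
        missing = [m for m in methods if m not in wide_all.columns]
        if missing:
            raise ValueError(f"feature table lacks methods {missing}")
        r_cells = []
        icc_site = {}
        for site, wide in wide_all.groupby(level="site_tag"):
            if len(wide) < min_patients:
                log.warning("site %s has %d patients for %s; skipped",
                            site, len(wide), metric)
                continue
            for m1, m2 in pairs:
                r = pearson_r(wide[m1], wide[m2])
                r_cells.append(r)
                records.append(PairAgreement(
                    (m1, m2), site, metric, r, len(wide),
                    ba=bland_altman(wide[m1].to_numpy(), wide[m2].to_numpy())))
            icc_site[site] = (icc_absolute_agreement(wide[list(methods)].to_numpy())
                              if len(wide) >= 5 else float("nan"))
        mean_r, cv_r = average_and_cv(r_cells)
        summaries.append(AgreementSummary(metric, mean_r, cv_r, icc_site))
    summaries.sort(key=lambda s: -s.mean_r)
    for i, s in enumerate(summaries):
        s.rank = i + 1
    return summaries, records


def summaries_frame(summaries: list[AgreementSummary]) -> pd.DataFrame:
    rows = [dict(metric_name=s.metric_name, mean_r=s.mean_r,
                 cv_r_pct=s.cv_r_pct, rank=s.rank,
                 **{f"icc_site_{k}": v for k, v in sorted(s.icc_per_site.items())})
            for s in summaries]
    return pd.DataFrame(rows)


def pairs_frame(records: list[PairAgreement]) -> pd.DataFrame:
    rows = [dict(metric_name=p.metric_name, site_tag=p.site_tag,
                 method_1=p.method_pair[0], method_2=p.method_pair[1],
                 r=p.r, n=p.n, **p.ba) for p in records]
    return pd.DataFrame(rows)
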