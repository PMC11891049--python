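"""First-order histogram radiomics of IVIM parameter maps.

Mirrors a fixed-range, fixed-bin histogram module: each parameter map is
binned into 100 equal-width bins over a fixed physical range (f_p: 0-1,
D_p: 0-0.1 mm²/s, D_t: 0-0.003 mm²/s) and the first-order features
(minimum, maximum, mean, variance, skewness, kurtosis) are computed from
the binned representation — bin centers weighted by counts — not from the
raw voxel values. Quantization error is therefore at most half a bin width
on location features; tests quantify it.

Voxels outside the range (or flagged unusable by the fitter) are excluded
per parameter and tracked as the utilization fraction.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import HISTOGRAM_RANGES

__all__ = [
    "HistogramSpec", "FirstOrderFeatures", "DEFAULT_SPECS", "METRICS",
    "build_histogram", "first_order_features", "features_for_map",
    "feature_table",
]

PARAMETERS = ("f_p", "D_p", "D_t")


@dataclass(frozen=True)
class HistogramSpec:
    parameter_tag: str
    range_min: float
    range_max: float
    n_bins: int = 100

    def __post_init__(self) -> None:
        if not self.range_max > self.range_min:
            raise ValueError("range_max must exceed range_min")
        if self.n_bins < 1:
            raise ValueError("n_bins must be positive")

    @property
    def bin_width(self) -> float:
        return (self.range_max - self.range_min) / self.n_bins


DEFAULT_SPECS: dict[str, HistogramSpec] = {
    par: HistogramSpec(par, lo, hi) for par, (lo, hi) in HISTOGRAM_RANGES.items()
}

#: the 16 reported metrics (min is computed for every parameter but
#: headlined only for D_t, whose minimum is not pinned at zero)
METRICS: tuple[str, ...] = (
    "D_t_min", "D_t_max", "D_t_mean", "D_t_variance", "D_t_skew", "D_t_kurt",
    "f_p_max", "f_p_mean", "f_p_variance", "f_p_skew", "f_p_kurt",
    "D_p_max", "D_p_mean", "D_p_variance", "D_p_skew", "D_p_kurt",
)

_FEATURE_SUFFIX = {"min": "minimum", "max": "maximum", "mean": "mean",
                   "variance": "variance", "skew": "skewness",
                   "kurt": "kurtosis"}


@dataclass
class FirstOrderFeatures:
    """First-order features of one parameter's binned value distribution."""

    minimum: float
    maximum: float
    mean: float
    variance: float
    skewness: float
    kurtosis: float
    utilization: float
    n_used: int
    defined: bool = True          # False when the histogram is empty
    degenerate: bool = False      # True when variance == 0 (skew/kurt = 0)

    def metric(self, suffix: str) -> float:
        return getattr(self, _FEATURE_SUFFIX[suffix])


def build_histogram(values, spec: HistogramSpec):
    """Fixed-range equal-width histogram.

    Bins are half-open [edge_i, edge_{i+1}) with the last bin closed, so a
    value exactly at ``range_max`` is counted. Values outside the range are
    excluded (they reduce utilization, not the bin counts).
    """
    vals = np.asarray(values, dtype=float).ravel()
    edges = np.linspace(spec.range_min, spec.range_max, spec.n_bins + 1)
    counts, _ = np.histogram(vals, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return counts, centers


def first_order_features(counts, bin_centers, spec: HistogramSpec,
                         n_total: int | None = None,
                         excess_kurtosis: bool = False) -> FirstOrderFeatures:
    """Features of the binned distribution (centers weighted by counts).

    Moments are population moments of the histogram; kurtosis is the
    non-excess ratio m4/m2² by default. With zero used voxels all features
    are NaN and ``defined`` is False; with zero variance, skewness and
    kurtosis are reported as 0 and flagged degenerate.
    """
    counts = np.asarray(counts)
    n_used = int(counts.sum())
    n_total = n_used if n_total is None else int(n_total)
    util = n_used / n_total if n_total > 0 else 0.0
    if n_used == 0:
        nan = float("nan")
        return FirstOrderFeatures(nan, nan, nan, nan, nan, nan, util, 0,
                                  defined=False)
    occ = np.flatnonzero(counts)
    w = counts / n_used
    mean = float(w @ bin_centers)
    dev = bin_centers - mean
    m2 = float(w @ dev ** 2)
    feats = dict(minimum=float(bin_centers[occ[0]]),
                 maximum=float(bin_centers[occ[-1]]),
                 mean=mean, variance=m2)
    if m2 > 0:
        m3 = float(w @ dev ** 3)
        m4 = float(w @ dev ** 4)
        skew = m3 / m2 ** 1.5
        kurt = m4 / m2 ** 2 - (3.0 if excess_kurtosis else 0.0)
        return FirstOrderFeatures(**feats, skewness=skew, kurtosis=kurt,
                                  utilization=util, n_used=n_used)
    return FirstOrderFeatures(**feats, skewness=0.0, kurtosis=0.0,
                              utilization=util, n_used=n_used,
                              degenerate=True)


def features_for_map(pmap, specs: dict[str, HistogramSpec] | None = None,
                     excess_kurtosis: bool = False
                     ) -> dict[str, FirstOrderFeatures]:
    """Per-parameter first-order features of one lesion's parameter map.

    Exclusion is per parameter: a voxel flagged out of range for D_p still
    contributes to the D_t and f_p histograms.
    """
    specs = specs or DEFAULT_SPECS
    out: dict[str, FirstOrderFeatures] = {}
    n_total = len(pmap)
    for par in PARAMETERS:
        vals = pmap.values(par)[pmap.in_range(par)]
        counts, centers = build_histogram(vals, specs[par])
        out[par] = first_order_features(counts, centers, specs[par],
                                        n_total=n_total,
                                        excess_kurtosis=excess_kurtosis)
    return out


def feature_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble a tidy per-(patient, method, metric) feature table.

    Each input row is the dict produced by :func:`study_features_row`-style
    callers: patient metadata plus a features dict per parameter.
    """
    recs = []
    for r in rows:
        feats: dict[str, FirstOrderFeatures] = r["features"]
        for metric in METRICS:
            par, suffix = metric.rsplit("_", 1)
            f = feats[par]
            recs.append(dict(patient_id=r["patient_id"], site_tag=r["site_tag"],
                             label=r["label"], method_tag=r["method_tag"],
                             metric_name=metric, value=f.metric(suffix),
                             utilization=f.utilization, n_used=f.n_used))
    return pd.DataFrame.from_records(recs)
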