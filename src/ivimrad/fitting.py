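"""Voxelwise IVIM parameter estimation.

Three production estimators emulate the algorithm families of widely used
analysis packages, plus a brute-force oracle for testing:

``seg_a``, ``seg_b``
    Iterative least-squares segmented fitting. Step 1 estimates D_t and the
    tissue intercept by ordinary least squares of ln(S) on b over the
    high-b regime (b >= 200 s/mm² by default, above the pseudodiffusion
    regime); Step 2 sets f_p = 1 - intercept_fraction; Step 3 estimates D_p
    by 1-D bounded least squares with f_p, D_t frozen. The three steps are
    then repeated after subtracting the estimated perfusion component from
    the data (the fixed point of this refinement on noiseless data is the
    generating parameter set; without it the high-b log-linear stage is
    biased whenever the perfusion signal has not fully decayed by the
    threshold). The variants differ in the final step: ``seg_a`` keeps the
    1-D D_p fit, ``seg_b`` jointly refines (f_p, D_p) by bounded nonlinear
    least squares with D_t frozen. ``seg_a`` additionally flags voxels
    whose D_p lands on the fit bound as unusable, emulating the more
    aggressive outlier rejection observed for that software family.

``bayes``
    Grid-based Bayesian posterior mean, see :mod:`ivimrad.bayes`.

``oracle``
    Multi-start full nonlinear least squares over all four parameters;
    recovers the generating parameters exactly on noiseless data.

Fitting operates on S / S(b=0) ratios; the measured b=0 signal pins the
amplitude (the oracle refits it). D_p fit bounds ([0, 0.3] mm²/s) are wider
than the histogram range [0, 0.1] so out-of-range voxels can occur.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .schemes import BValueScheme
from .signal import IVIMParams

__all__ = [
    "VoxelDecay", "FitResult", "ParameterMap", "FitOptions",
    "fit_monoexp_loglinear", "fit_segmented_lsq", "fit_full_nlls_oracle",
    "fit_roi", "METHOD_TAGS",
]

METHOD_TAGS = ("seg_a", "seg_b", "bayes", "oracle")

#: fixed-range histogram supports per parameter (also the Bayesian prior
#: support for D_p and D_t); f_p dimensionless, D's in mm²/s
HISTOGRAM_RANGES = {"f_p": (0.0, 1.0), "D_p": (0.0, 0.1), "D_t": (0.0, 0.003)}

_EPS_FRAC = 1e-6          # signal clip: eps = 1e-6 * S0 before log transform
_FP_TINY = 1e-9           # below this, D_p is unidentifiable


@dataclass(frozen=True)
class VoxelDecay:
    """One voxel's magnitude signal across a b-value scheme."""

    signals: np.ndarray
    scheme: BValueScheme

    def __post_init__(self) -> None:
        s = np.asarray(self.signals, dtype=float)
        object.__setattr__(self, "signals", s)
        if s.ndim != 1 or len(s) != len(self.scheme):
            raise ValueError(
                f"signals length {len(s)} does not match scheme length {len(self.scheme)}")
        if np.any(s <= 0):
            raise ValueError("signals must be strictly positive")


@dataclass
class FitResult:
    """A per-voxel estimate with validity bookkeeping.

    ``in_range`` holds one flag per parameter against the fixed histogram
    ranges (a voxel can be usable for D_t but not D_p). Non-converged fits
    still carry the best iterate, flagged by ``converged=False``.
    """

    params: IVIMParams
    in_range: dict[str, bool]
    converged: bool
    residual_norm: float
    method_tag: str
    extras: dict = field(default_factory=dict)

    def value(self, parameter: str) -> float:
        return getattr(self.params, parameter)


@dataclass
class ParameterMap:
    """Per-voxel fit results for one lesion and one method."""

    method_tag: str
    results: list[FitResult]
    patient_id: str = ""

    def __len__(self) -> int:
        return len(self.results)

    def values(self, parameter: str) -> np.ndarray:
        return np.array([r.value(parameter) for r in self.results])

    def in_range(self, parameter: str) -> np.ndarray:
        return np.array([r.in_range[parameter] for r in self.results], dtype=bool)


def parameter_map_from_records(records, method_tag: str,
                               patient_id: str = "") -> ParameterMap:
    """Rebuild a ParameterMap from flat per-voxel records (e.g. CSV rows)
    with keys f_p, D_p, D_t, S0, *_in_range, converged, residual_norm."""
    results = [FitResult(
        params=IVIMParams(r["f_p"], r["D_p"], r["D_t"], r.get("S0", 1.0)),
        in_range={p: bool(r[f"{p}_in_range"]) for p in ("f_p", "D_p", "D_t")},
        converged=bool(r["converged"]),
        residual_norm=float(r.get("residual_norm", float("nan"))),
        method_tag=method_tag) for r in records]
    return ParameterMap(method_tag, results, patient_id)


@dataclass(frozen=True)
class FitOptions:
    """Numerical settings shared by the segmented fitters."""

    b_threshold: float = 200.0     # s/mm²; start of the diffusion-only regime
    max_refine: int = 50           # perfusion-subtraction refinement passes
    refine_tol: float = 1e-4       # per-voxel relative-change stop rule
    dp_init: float = 0.01          # mm²/s, reported when D_p is unidentifiable
    dp_bounds: tuple[float, float] = (0.0, 0.3)
    dt_bounds: tuple[float, float] = (0.0, 0.01)


# ---------------------------------------------------------------------------
# log-linear high-b stage

def fit_monoexp_loglinear(decay: VoxelDecay, b_threshold: float = 200.0
                          ) -> tuple[float, float]:
    """Monoexponential log-linear fit over the high-b regime.

    Returns (D_t, intercept_fraction) where the intercept fraction is the
    back-extrapolated b=0 amplitude of the tissue compartment divided by
    the measured b=0 signal.
    """
    b = decay.scheme.b_values
    dt, frac = _loglinear_batch(decay.signals[None, :] / decay.signals[0],
                                b, b >= b_threshold, clip_dt=None)
    return float(dt[0]), float(frac[0])


def _high_mask(scheme: BValueScheme, b_threshold: float) -> np.ndarray:
    mask = scheme.b_values >= b_threshold
    if mask.sum() < 2:
        raise ValueError(
            f"scheme {scheme.site_tag}/{scheme.variant_index} has "
            f"{int(mask.sum())} b-values >= {b_threshold}; need at least 2")
    return mask


def _loglinear_batch(s: np.ndarray, b: np.ndarray, high: np.ndarray,
                     clip_dt: tuple[float, float] | None):
    """OLS of ln(s) on b restricted to ``high``; s is (V, N) ratio data."""
    if high.sum() < 2:
        raise ValueError(f"need at least 2 b-values above threshold; got {int(high.sum())}")
    x = b[high]
    # closed-form OLS as per-row weighted sums: reductions run strictly
    # within each voxel's row, so results are independent of batch size
    xbar = x.mean()
    w_slope = (x - xbar) / np.sum((x - xbar) ** 2)
    y = np.log(np.clip(s[:, high], _EPS_FRAC, None))
    slope = (y * w_slope).sum(axis=1)
    inter = y.mean(axis=1) - slope * xbar
    dt = -slope
    if clip_dt is not None:
        dt = np.clip(dt, *clip_dt)
    return dt, np.exp(inter)


# ---------------------------------------------------------------------------
# 1-D bounded least squares for D_p (vectorized grid + golden section)

_DP_GRID_N = 48
_GOLD = (np.sqrt(5.0) - 1.0) / 2.0


def _dp_objective(dp, s, b, fp, et):
    """Sum-of-squares residual as a function of D_p, other params frozen."""
    ep = np.exp(-np.multiply.outer(dp, b))
    r = fp[:, None] * ep + (1.0 - fp)[:, None] * et - s
    return np.einsum("vn,vn->v", r, r)


def _fit_dp_batch(s, b, fp, dt, dp_lo, dp_hi, n_golden=40):
    """Per-voxel bounded 1-D least squares over D_p.

    Coarse shared log-grid bracket followed by golden-section refinement;
    unimodality of the 1-D profile holds across the bracket in practice.
    Voxels with f_p ~ 0 are left to the caller (D_p unidentifiable).
    """
    et = np.exp(-np.multiply.outer(dt, b))
    grid = np.geomspace(max(dp_lo, 1e-5), dp_hi, _DP_GRID_N)
    # separable SSR over the shared grid: fp^2*|ep|^2 - 2*fp*ep.(s-(1-fp)et)
    ep_g = np.exp(-np.outer(grid, b))                       # (G, N)
    pp = np.einsum("gn,gn->g", ep_g, ep_g)
    q = np.einsum("vn,gn->vg", s - (1.0 - fp)[:, None] * et, ep_g)  # (V, G)
    h = fp[:, None] * pp[None, :] - 2.0 * q                 # argmin equiv.
    idx = np.argmin(h, axis=1)
    lo = grid[np.maximum(idx - 1, 0)]
    hi = grid[np.minimum(idx + 1, _DP_GRID_N - 1)]
    lo = np.where(idx == 0, dp_lo, lo)
    a, c = lo.copy(), hi.copy()
    x1 = c - _GOLD * (c - a)
    x2 = a + _GOLD * (c - a)
    f1 = _dp_objective(x1, s, b, fp, et)
    f2 = _dp_objective(x2, s, b, fp, et)
    for _ in range(n_golden):
        t = f1 < f2
        a_n = np.where(t, a, x1)
        c_n = np.where(t, x2, c)
        x1_n = np.where(t, c_n - _GOLD * (c_n - a_n), x2)
        x2_n = np.where(t, x1, a_n + _GOLD * (c_n - a_n))
        fe = _dp_objective(np.where(t, x1_n, x2_n), s, b, fp, et)
        f1, f2 = np.where(t, fe, f2), np.where(t, f1, fe)
        a, c, x1, x2 = a_n, c_n, x1_n, x2_n
    return (a + c) / 2.0


# ---------------------------------------------------------------------------
# segmented fitters

def _segmented_batch(S: np.ndarray, scheme: BValueScheme, variant: str,
                     opt: FitOptions):
    """Vectorized iterative segmented fit. S is (V, N) raw magnitudes.

    Per-voxel refinement freezes a voxel once its (D_t, f_p) update falls
    below ``refine_tol``, so each voxel's estimate is independent of which
    other voxels share the batch.
    """
    if variant not in ("seg_a", "seg_b"):
        raise ValueError(f"variant must be 'seg_a' or 'seg_b'; got {variant!r}")
    b = scheme.b_values
    high = _high_mask(scheme, opt.b_threshold)
    s0 = S[:, 0].astype(float)
    s = S / s0[:, None]
    V = s.shape[0]

    dt, frac = _loglinear_batch(s, b, high, clip_dt=opt.dt_bounds)
    fp = np.clip(1.0 - frac, 0.0, 1.0)
    dp = np.full(V, opt.dp_init)
    idf = fp > _FP_TINY                      # identifiable D_p
    if idf.any():
        dp[idf] = _fit_dp_batch(s[idf], b, fp[idf], dt[idf], *opt.dp_bounds)

    active = np.ones(V, dtype=bool)
    converged = np.zeros(V, dtype=bool)
    for _ in range(opt.max_refine):
        if not active.any():
            break
        ia = np.flatnonzero(active)
        sa = s[ia]
        corr = np.clip(sa - fp[ia, None] * np.exp(-np.multiply.outer(dp[ia], b)),
                       _EPS_FRAC, None)
        dt_new, frac_new = _loglinear_batch(corr, b, high, clip_dt=opt.dt_bounds)
        fp_new = np.clip(1.0 - frac_new, 0.0, 1.0)
        dp_new = np.full(len(ia), opt.dp_init)
        m = fp_new > _FP_TINY
        if m.any():
            dp_new[m] = _fit_dp_batch(sa[m], b, fp_new[m], dt_new[m], *opt.dp_bounds)
        delta = np.maximum(np.abs(dt_new - dt[ia]) / np.maximum(dt[ia], 1e-6),
                           np.abs(fp_new - fp[ia]))
        dt[ia], fp[ia], dp[ia] = dt_new, fp_new, dp_new
        done = delta < opt.refine_tol
        converged[ia[done]] = True
        active[ia[done]] = False
    # voxels that exhausted max_refine keep their best iterate, flagged

    if variant == "seg_b":
        for v in np.flatnonzero(fp > _FP_TINY):
            et = np.exp(-b * dt[v])
            sv = s[v]

            def resid(p):
                return p[0] * np.exp(-b * p[1]) + (1.0 - p[0]) * et - sv

            def jac(p):
                ep = np.exp(-b * p[1])
                return np.column_stack([ep - et, -b * p[0] * ep])

            x0 = [min(max(fp[v], 1e-6), 1 - 1e-9),
                  min(max(dp[v], 1e-6), opt.dp_bounds[1] - 1e-9)]
            sol = least_squares(resid, x0, jac=jac,
                                bounds=([0.0, 0.0], [1.0, opt.dp_bounds[1]]),
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
            fp[v], dp[v] = sol.x

    ep = np.exp(-np.multiply.outer(dp, b))
    et = np.exp(-np.multiply.outer(dt, b))
    resid = fp[:, None] * ep + (1.0 - fp)[:, None] * et - s
    rnorm = np.einsum("vn,vn->v", resid, resid)

    at_bound = dp >= opt.dp_bounds[1] * (1.0 - 1e-6)
    lo, hi = HISTOGRAM_RANGES["D_p"]
    dp_ok = (dp >= lo) & (dp <= hi)
    if variant == "seg_a":
        dp_ok &= ~at_bound
    tlo, thi = HISTOGRAM_RANGES["D_t"]
    dt_ok = (dt >= tlo) & (dt <= thi)
    fp_ok = (fp >= 0.0) & (fp <= 1.0)
    return dict(fp=fp, dp=dp, dt=dt, s0=s0, rnorm=rnorm, converged=converged,
                fp_ok=fp_ok, dp_ok=dp_ok, dt_ok=dt_ok)


def _pack_results(raw: dict, method_tag: str) -> list[FitResult]:
    out = []
    for v in range(len(raw["fp"])):
        out.append(FitResult(
            params=IVIMParams(float(raw["fp"][v]), float(raw["dp"][v]),
                              float(raw["dt"][v]), float(raw["s0"][v])),
            in_range={"f_p": bool(raw["fp_ok"][v]), "D_p": bool(raw["dp_ok"][v]),
                      "D_t": bool(raw["dt_ok"][v])},
            converged=bool(raw["converged"][v]),
            residual_norm=float(raw["rnorm"][v]),
            method_tag=method_tag,
            extras={k: float(raw[k][v]) for k in raw.get("extra_keys", ())},
        ))
    return out


def fit_segmented_lsq(decay: VoxelDecay, variant: str = "seg_a",
                      options: FitOptions | None = None) -> FitResult:
    """Segmented least-squares fit of a single voxel (see module docstring)."""
    opt = options or FitOptions()
    raw = _segmented_batch(decay.signals[None, :], decay.scheme, variant, opt)
    return _pack_results(raw, variant)[0]


# ---------------------------------------------------------------------------
# full-NLLS oracle

_ORACLE_STARTS = [(f0, p0, t0)
                  for f0 in (0.05, 0.3)
                  for p0 in (0.003, 0.03)
                  for t0 in (0.0005, 0.002)]


def fit_full_nlls_oracle(decay: VoxelDecay) -> FitResult:
    """Global biexponential fit by multi-start bounded nonlinear least squares.

    Deterministic: the 8 coarse-grid starts are fixed, the winner is the
    lowest residual norm with ties broken by the lowest D_p (the less
    perfused interpretation).
    """
    b = decay.scheme.b_values
    s = decay.signals / decay.signals[0]

    def resid(p):
        fp, dp, dt, a = p
        return a * (fp * np.exp(-b * dp) + (1 - fp) * np.exp(-b * dt)) - s

    def jac(p):
        fp, dp, dt, a = p
        ep, et = np.exp(-b * dp), np.exp(-b * dt)
        return np.column_stack([a * (ep - et), -a * fp * b * ep,
                                -a * (1 - fp) * b * et, fp * ep + (1 - fp) * et])

    cands = []
    for f0, p0, t0 in _ORACLE_STARTS:
        sol = least_squares(
            resid, [f0, p0, t0, 1.0], jac=jac,
            bounds=([0.0, 0.0, 0.0, 0.1], [1.0, 0.3, 0.01, 10.0]),
            x_scale=[0.1, 0.01, 0.001, 1.0],
            xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000)
        x = sol.x
        if x[1] < x[2]:
            # the model is symmetric under (f_p, D_p) <-> (1-f_p, D_t);
            # canonicalize to the D_p >= D_t compartment labelling
            x = np.array([1.0 - x[0], x[2], x[1], x[3]])
        cands.append((2.0 * sol.cost, x, sol.status > 0))
    best_ssr = min(c[0] for c in cands)
    tol = best_ssr * 1e-9 + 1e-28
    near = [c for c in cands if c[0] <= best_ssr + tol]
    ssr, x, ok = min(near, key=lambda c: c[1][1])   # lowest D_p among ties
    fp, dp, dt, a = x
    s0 = a * decay.signals[0]
    return FitResult(
        params=IVIMParams(float(fp), float(dp), float(dt), float(s0)),
        in_range={"f_p": True,
                  "D_p": HISTOGRAM_RANGES["D_p"][0] <= dp <= HISTOGRAM_RANGES["D_p"][1],
                  "D_t": HISTOGRAM_RANGES["D_t"][0] <= dt <= HISTOGRAM_RANGES["D_t"][1]},
        converged=bool(ok), residual_norm=float(ssr), method_tag="oracle")


# ---------------------------------------------------------------------------
# ROI driver

def fit_roi(signals: np.ndarray, scheme: BValueScheme, method_tag: str,
            options: FitOptions | None = None, patient_id: str = "",
            bayes_options=None) -> ParameterMap:
    """Fit every voxel of a lesion ROI independently.

    ``signals`` is (n_voxels, n_b). The result is order-independent: each
    voxel's estimate is a function of that voxel's decay only.
    """
    S = np.asarray(signals, dtype=float)
    if S.ndim != 2 or S.shape[1] != len(scheme):
        raise ValueError("signals must be (n_voxels, n_b) matching the scheme")
    if np.any(S <= 0):
        raise ValueError("signals must be strictly positive")
    opt = options or FitOptions()
    if method_tag in ("seg_a", "seg_b"):
        raw = _segmented_batch(S, scheme, method_tag, opt)
        results = _pack_results(raw, method_tag)
    elif method_tag == "bayes":
        from .bayes import fit_bayesian_batch
        results = fit_bayesian_batch(S, scheme, options=bayes_options)
    elif method_tag == "oracle":
        results = [fit_full_nlls_oracle(VoxelDecay(S[v], scheme))
                   for v in range(S.shape[0])]
    else:
        raise ValueError(f"unknown method_tag {method_tag!r}; valid: {METHOD_TAGS}")
    return ParameterMap(method_tag, results, patient_id)
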