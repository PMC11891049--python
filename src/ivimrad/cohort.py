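"""Seeded synthetic multi-site breast-lesion IVIM cohorts.

Generates lesions with known ground truth that emulate the published study
conditions: per-site benign/malignant counts, per-site b-value schemes
(Site A's five sub-schemes assigned proportionally to their usage counts),
class- and site-specific IVIM parameter distributions taken from the
reference-software columns of the published per-site means, right-skewed
ROI sizes matched to the published voxel-count moments, and Rician
magnitude noise.

Each lesion is a "bag of voxels": ROI geometry carries no information for
any downstream statistic, so none is simulated (a toy 3-D layout exists
only for NIfTI round-trips, see :mod:`ivimrad.nifti_io`).
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .schemes import BValueScheme, SITES, SITE_A_VARIANT_COUNTS, site_bvalue_scheme
from .signal import IVIMParams, add_rician_noise

__all__ = [
    "CohortConfig",
    "LesionSpec",
    "SyntheticCohort",
    "sample_lesion",
    "generate_cohort",
    "TRUTH_DISTRIBUTIONS",
    "ROI_SIZE_MOMENTS",
    "DEFAULT_SITE_COUNTS",
]

# ---------------------------------------------------------------------------
# Published study conditions (reference software column).
# f_p as a fraction; D_p and D_t in mm²/s. Values are across-patient
# mean ± SD of ROI means per (site, class).
TRUTH_DISTRIBUTIONS: dict[tuple[str, str], dict[str, tuple[float, float]]] = {
    ("A", "benign"):    {"f_p": (0.1579, 0.0987), "D_p": (10.57e-3, 3.83e-3), "D_t": (1.26e-3, 0.29e-3)},
    ("A", "malignant"): {"f_p": (0.1385, 0.0502), "D_p": (12.02e-3, 3.12e-3), "D_t": (1.20e-3, 0.39e-3)},
    ("B", "benign"):    {"f_p": (0.1862, 0.0749), "D_p": (6.07e-3, 2.34e-3), "D_t": (1.04e-3, 0.33e-3)},
    ("B", "malignant"): {"f_p": (0.2066, 0.0715), "D_p": (7.06e-3, 2.02e-3), "D_t": (0.88e-3, 0.29e-3)},
    ("C", "benign"):    {"f_p": (0.1277, 0.0695), "D_p": (18.02e-3, 8.47e-3), "D_t": (1.36e-3, 0.40e-3)},
    ("C", "malignant"): {"f_p": (0.1141, 0.0491), "D_p": (16.23e-3, 5.94e-3), "D_t": (0.93e-3, 0.29e-3)},
}

#: ROI voxel count mean ± SD per (site, class).
ROI_SIZE_MOMENTS: dict[tuple[str, str], tuple[float, float]] = {
    ("A", "benign"): (201.0, 143.0),
    ("A", "malignant"): (1363.0, 1644.0),
    ("B", "benign"): (51.0, 101.0),
    ("B", "malignant"): (34.0, 28.0),
    ("C", "benign"): (33.0, 40.0),
    ("C", "malignant"): (56.0, 69.0),
}

#: (n_benign, n_malignant) per site in the default cohort (302 patients).
DEFAULT_SITE_COUNTS: dict[str, tuple[int, int]] = {
    "A": (12, 46),
    "B": (70, 19),
    "C": (38, 117),
}

# truncation box for ground-truth parameters (matches histogram ranges)
_BOX = {"f_p": (0.0, 1.0), "D_p": (0.0, 0.1), "D_t": (0.0, 0.003)}
_MIN_VOXELS = 3  # every ROI contains at least 3 voxels


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings. Defaults reproduce the study conditions."""

    site_counts: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_SITE_COUNTS))
    snr: float = 40.0                 # signal-to-noise ratio at b = 0
    variability: float = 0.10         # intra-lesion multiplicative SD fraction
    s0: float = 100.0                 # unweighted amplitude, arbitrary units

    def validate(self) -> "CohortConfig":
        for site, (nb, nm) in self.site_counts.items():
            if site not in SITES:
                raise ValueError(f"unknown site {site!r}")
            if nb < 1 or nm < 1:
                raise ValueError(f"counts for site {site} must be >= 1; got {nb}/{nm}")
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        if self.variability < 0:
            raise ValueError("variability must be non-negative")
        if not self.s0 > 0:
            raise ValueError("s0 must be positive")
        return self

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class LesionSpec:
    """One patient's lesion: ground truth plus acquisition context."""

    patient_id: str
    site_tag: str
    label: str                        # "benign" | "malignant"
    scheme: BValueScheme
    truth_map: list[IVIMParams]       # per-voxel ground truth
    snr: float

    @property
    def n_voxels(self) -> int:
        return len(self.truth_map)


@dataclass
class SyntheticCohort:
    lesions: list[LesionSpec]
    noisy_signals: dict[str, np.ndarray]   # patient_id -> (n_voxels, n_b)
    seed: int
    config: CohortConfig

    def __len__(self) -> int:
        return len(self.lesions)


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float) -> float:
    """Rejection-sampled truncated normal (the truncation is always mild)."""
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return float(np.clip(mean, lo, hi))


def _sample_center(rng: np.random.Generator, site: str, label: str) -> dict[str, float]:
    """Patient-level parameter center; D_p >= D_t enforced by resampling."""
    dist = TRUTH_DISTRIBUTIONS[(site, label)]
    for _ in range(1000):
        c = {k: _trunc_normal(rng, *dist[k], *_BOX[k]) for k in ("f_p", "D_p", "D_t")}
        if c["D_p"] >= c["D_t"]:
            return c
    c["D_p"] = max(c["D_p"], c["D_t"])
    return c


def _sample_n_voxels(rng: np.random.Generator, site: str, label: str) -> int:
    """Lognormal matched by moments to the published ROI sizes, floored at 3."""
    mean, sd = ROI_SIZE_MOMENTS[(site, label)]
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    n = int(round(float(rng.lognormal(mu, np.sqrt(sigma2)))))
    return max(n, _MIN_VOXELS)


def sample_lesion(site_tag: str, label: str, rng: np.random.Generator,
                  config: CohortConfig, patient_id: str = "P000",
                  scheme: BValueScheme | None = None) -> LesionSpec:
    """Draw one lesion's ground truth.

    The patient-level center is drawn from the published per-(site, class)
    mean/SD (truncated to physical ranges, D_p >= D_t by resampling); voxel
    values are the center perturbed multiplicatively by independent Gaussian
    factors ``1 + variability * z`` per parameter, re-truncated.
    """
    if (site_tag, label) not in TRUTH_DISTRIBUTIONS:
        raise KeyError(
            f"no parameter distribution for site={site_tag!r}, label={label!r}")
    if scheme is None:
        scheme = site_bvalue_scheme(site_tag, 1)
    center = _sample_center(rng, site_tag, label)
    n_vox = _sample_n_voxels(rng, site_tag, label)
    v = config.variability
    truth: list[IVIMParams] = []
    for _ in range(n_vox):
        for _try in range(1000):
            vals = {k: center[k] * (1.0 + v * rng.standard_normal())
                    for k in ("f_p", "D_p", "D_t")}
            ok = all(_BOX[k][0] <= vals[k] <= _BOX[k][1] for k in vals)
            if ok and vals["D_p"] >= vals["D_t"]:
                break
        else:
            vals = {k: float(np.clip(center[k], *_BOX[k])) for k in center}
            vals["D_p"] = max(vals["D_p"], vals["D_t"])
        truth.append(IVIMParams(vals["f_p"], vals["D_p"], vals["D_t"], config.s0))
    return LesionSpec(patient_id, site_tag, label, scheme, truth, config.snr)


def _site_a_variant_sequence(n: int) -> list[int]:
    """Deterministic proportional (round-robin) sub-scheme assignment.

    Quotas follow the published usage counts by largest remainder; the
    merged order interleaves variants so both classes receive every variant.
    """
    counts = np.asarray(SITE_A_VARIANT_COUNTS, dtype=float)
    quota = counts / counts.sum() * n
    base = np.floor(quota).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    for i in range(rem):
        base[order[i]] += 1
    slots = [((j + 0.5) / base[v], v) for v in range(5) for j in range(base[v])]
    slots.sort()
    return [v + 1 for _, v in slots]


def generate_cohort(config: CohortConfig, seed: int) -> SyntheticCohort:
    """Generate a full multi-site cohort with noisy magnitude signals.

    Reproducible: a pure function of (config, seed). Per-lesion random
    streams are split from the master seed by counter so that the draw for
    one lesion does not depend on any other lesion.
    """
    config.validate()
    lesions: list[LesionSpec] = []
    signals: dict[str, np.ndarray] = {}
    for si, site in enumerate(sorted(config.site_counts)):
        nb, nm = config.site_counts[site]
        n_site = nb + nm
        variants = (_site_a_variant_sequence(n_site) if site == "A"
                    else [1] * n_site)
        for i in range(n_site):
            label = "benign" if i < nb else "malignant"
            pid = f"{site}{i + 1:03d}"
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(si, i)))
            scheme = site_bvalue_scheme(site, variants[i])
            lesion = sample_lesion(site, label, rng, config, pid, scheme)
            b = scheme.b_values
            clean = np.stack([
                p.S0 * (p.f_p * np.exp(-b * p.D_p) + (1 - p.f_p) * np.exp(-b * p.D_t))
                for p in lesion.truth_map])
            signals[pid] = add_rician_noise(clean, config.snr, rng, s0=config.s0)
            lesions.append(lesion)
    return SyntheticCohort(lesions, signals, seed, config)
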