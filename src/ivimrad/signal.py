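"""Biexponential IVIM signal model and Rician magnitude noise.

The two-compartment model of diffusion-weighted signal decay:

    S(b) = S0 * (f_p * exp(-b * D_p) + (1 - f_p) * exp(-b * D_t))

with perfusion fraction ``f_p`` (dimensionless), pseudo-diffusion ``D_p``
and tissue diffusivity ``D_t`` (both mm²/s), and unweighted amplitude
``S0``. Magnitude MRI noise is Rician: the modulus of the clean signal plus
complex Gaussian noise.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["IVIMParams", "ivim_signal", "add_rician_noise"]


@dataclass(frozen=True)
class IVIMParams:
    """The IVIM parameter triple plus amplitude.

    Ground-truth objects must satisfy 0 <= f_p <= 1, D_p >= D_t >= 0 and
    S0 > 0; fitted estimates are represented elsewhere and may violate the
    compartment ordering.
    """

    f_p: float
    D_p: float
    D_t: float
    S0: float = 1.0

    def validate(self) -> "IVIMParams":
        if not 0.0 <= self.f_p <= 1.0:
            raise ValueError(f"f_p must lie in [0, 1]; got {self.f_p}")
        if not self.D_p >= self.D_t >= 0.0:
            raise ValueError(
                f"require D_p >= D_t >= 0; got D_p={self.D_p}, D_t={self.D_t}"
            )
        if not self.S0 > 0:
            raise ValueError(f"S0 must be positive; got {self.S0}")
        return self


def ivim_signal(params: IVIMParams, b) -> np.ndarray | float:
    """Evaluate the biexponential decay at diffusion weighting(s) ``b``.

    Parameters
    ----------
    params : IVIMParams
    b : float or array-like
        b-value(s), s/mm²; must be non-negative.

    Returns
    -------
    Signal in the same units as ``params.S0``; monotone non-increasing in b.
    """
    params.validate()
    b_arr = np.asarray(b, dtype=float)
    if np.any(b_arr < 0):
        raise ValueError("b-values must be non-negative")
    s = params.S0 * (
        params.f_p * np.exp(-b_arr * params.D_p)
        + (1.0 - params.f_p) * np.exp(-b_arr * params.D_t)
    )
    return s if np.ndim(b) else float(s)


def add_rician_noise(clean_signal, snr: float, rng: np.random.Generator,
                     s0: float | None = None) -> np.ndarray:
    """Corrupt a clean magnitude signal with Rician noise.

    Returns |clean + n1 + i*n2| with n1, n2 i.i.d. zero-mean Gaussian of
    standard deviation ``s0 / snr``. ``s0`` defaults to the maximum of the
    clean signal (the b=0 amplitude for a decay curve), so ``snr`` is the
    signal-to-noise ratio at b = 0.
    """
    clean = np.asarray(clean_signal, dtype=float)
    if np.any(clean < 0):
        raise ValueError("clean signal must be non-negative")
    if not snr > 0:
        raise ValueError(f"snr must be positive; got {snr}")
    sigma = (float(np.max(clean)) if s0 is None else float(s0)) / snr
    n1 = rng.normal(0.0, sigma, clean.shape)
    n2 = rng.normal(0.0, sigma, clean.shape)
    return np.hypot(clean + n1, n2)
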