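"""Site-specific diffusion-weighting (b-value) schemes.

Three clinical sites are modelled. Site A acquired with five different
b-value sub-schemes over the course of the study (usage counts 9/24/10/14/1
patients); Sites B and C each used a single scheme. b-values are in s/mm².
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BValueScheme", "site_bvalue_scheme", "SITE_A_VARIANT_COUNTS", "SITES"]

SITES = ("A", "B", "C")

# (site, variant) -> printed b-value list
_SCHEMES: dict[tuple[str, int], tuple[float, ...]] = {
    ("A", 1): (0, 30, 60, 90, 120, 250, 400, 600, 800),
    ("A", 2): (0, 30, 60, 90, 120, 400, 600, 800, 1000),
    ("A", 3): (0, 30, 60, 90, 120, 250, 450, 600, 800, 1000),
    ("A", 4): (0, 30, 60, 90, 120, 250, 400, 600, 800, 1000),
    ("A", 5): (0, 10, 30, 60, 90, 120, 200, 400, 600, 800, 1000),
    ("B", 1): (0, 100, 600, 800, 1000),
    ("C", 1): (0, 5, 10, 20, 30, 50, 70, 100, 200, 400, 600, 800, 1000),
}

#: number of Site A patients acquired with each sub-scheme (variants 1..5)
SITE_A_VARIANT_COUNTS = (9, 24, 10, 14, 1)


@dataclass(frozen=True)
class BValueScheme:
    """An ordered set of diffusion weightings for one acquisition.

    Attributes
    ----------
    site_tag : {"A", "B", "C"}
    variant_index : int
        1-based sub-scheme index (Site A has 5; B and C have 1).
    b_values : np.ndarray
        Strictly increasing, starting at 0, length >= 4; units s/mm².
    """

    site_tag: str
    variant_index: int
    b_values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        object.__setattr__(self, "b_values", b)
        if b.ndim != 1 or len(b) < 4:
            raise ValueError("b_values must be a 1-D array of length >= 4")
        if b[0] != 0:
            raise ValueError("first b-value must be 0")
        if np.any(np.diff(b) <= 0):
            raise ValueError("b_values must be strictly increasing")

    def __len__(self) -> int:
        return len(self.b_values)


def site_bvalue_scheme(site_tag: str, variant_index: int = 1) -> BValueScheme:
    """Return the printed b-value scheme for a site (and Site A sub-scheme).

    Raises
    ------
    ValueError
        For an unknown site or an invalid variant index, naming the valid
        options.
    """
    if site_tag not in SITES:
        raise ValueError(f"unknown site {site_tag!r}; valid sites: {SITES}")
    key = (site_tag, variant_index)
    if key not in _SCHEMES:
        n = 5 if site_tag == "A" else 1
        raise ValueError(
            f"site {site_tag} has variants 1..{n}; got variant_index={variant_index}"
        )
    return BValueScheme(site_tag, variant_index, np.array(_SCHEMES[key], dtype=float))
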