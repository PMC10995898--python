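"""Gel-lane densitometry for the structure-stability assay.

A lane profile is the per-row sum of intensities across the lane's column
window, with a rolling-ball-style baseline (1-D morphological opening)
subtracted and clipped at zero. Band windows along the migration axis are
supplied per lane (with roles: the single intact-structure band, plus
aggregate/other bands); the stability readout is the intact band's
integral divided by the total integral of all bands in the lane, which
cancels loading and concentration differences between lanes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .exceptions import InvalidInputError

__all__ = [
    "Band",
    "BandSet",
    "LaneProfile",
    "lane_profile",
    "band_integrals",
    "band_fraction",
]

BAND_ROLES = ("intact", "aggregate", "other")


@dataclass(frozen=True)
class Band:
    """Half-open window [start, end) on the migration axis with a role."""

    start: int
    end: int
    role: str

    def __post_init__(self) -> None:
        if self.role not in BAND_ROLES:
            raise InvalidInputError(f"band role must be one of {BAND_ROLES}")
        if not 0 <= self.start < self.end:
            raise InvalidInputError("band window must satisfy 0 <= start < end")


@dataclass
class BandSet:
    """Non-overlapping band windows for one lane; exactly one intact band."""

    bands: list[Band]

    def __post_init__(self) -> None:
        bands = sorted(self.bands, key=lambda b: b.start)
        if sum(b.role == "intact" for b in bands) != 1:
            raise InvalidInputError("exactly one band must have role 'intact'")
        for a, b in zip(bands, bands[1:]):
            if b.start < a.end:
                raise InvalidInputError("band windows must not overlap")
        self.bands = bands


@dataclass
class LaneProfile:
    """Background-corrected 1-D intensity profile along the migration axis."""

    positions: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        positions = np.asarray(self.positions)
        intensities = np.asarray(self.intensities, dtype=float)
        if positions.shape != intensities.shape or positions.ndim != 1:
            raise InvalidInputError("positions and intensities must be equal-length 1-D")
        if intensities.size and intensities.min() < 0:
            raise InvalidInputError("profile intensities must be >= 0")
        self.positions = positions
        self.intensities = intensities


def lane_profile(
    gel_image: np.ndarray,
    lane_bounds: tuple[int, int],
    baseline_width: int = 50,
) -> LaneProfile:
    """Extract one lane's baseline-corrected migration profile.

    Rows are summed across the lane's column window; a 1-D grey opening of
    width ``baseline_width`` (wider than any band) estimates the smooth
    baseline, which is subtracted and the result clipped at zero.
    """
    gel_image = np.asarray(gel_image, dtype=float)
    if gel_image.ndim != 2:
        raise InvalidInputError("gel_image must be 2-D")
    c0, c1 = lane_bounds
    if not (0 <= c0 < c1 <= gel_image.shape[1]):
        raise InvalidInputError("lane window outside image columns")
    profile = gel_image[:, c0:c1].sum(axis=1)
    if baseline_width > 1:
        baseline = ndi.grey_opening(profile, size=baseline_width)
        profile = profile - baseline
    return LaneProfile(np.arange(gel_image.shape[0]), np.clip(profile, 0.0, None))


def band_integrals(profile: LaneProfile, bands: BandSet):
    """Integral and lane fraction per band window.

    Returns a list of ``(role, start, end, integral, fraction)`` tuples.
    With zero total band mass the fractions are NaN (warned, not raised).
    """
    n = profile.intensities.size
    integrals = []
    for band in bands.bands:
        if band.end > n:
            raise InvalidInputError("band window outside profile range")
        integrals.append(float(profile.intensities[band.start:band.end].sum()))
    total = sum(integrals)
    if total <= 0:
        warnings.warn("total band mass is zero; fractions undefined", stacklevel=2)
        fractions = [float("nan")] * len(integrals)
    else:
        fractions = [i / total for i in integrals]
    return [
        (band.role, band.start, band.end, integral, fraction)
        for band, integral, fraction in zip(bands.bands, integrals, fractions)
    ]


def band_fraction(profile: LaneProfile, bands: BandSet) -> float:
    """Fraction of lane band mass in the intact-structure band."""
    for role, _, _, _, fraction in band_integrals(profile, bands):
        if role == "intact":
            return fraction
    raise InvalidInputError("no intact band defined")  # pragma: no cover
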