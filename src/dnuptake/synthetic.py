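"""Synthetic inputs with known ground truth for every pipeline stage.

Emulates the data the quantification pipeline consumes:

* three-channel cell fields — elliptical cells with a membrane-localized
  Gaussian ring (surface channel), diffraction-limited intracellular
  puncta with a programmed intranuclear fraction (internalized channel),
  and filled elliptical nuclei (nuclear channel); a flat background offset
  and shot-type or Gaussian read noise are applied only after the true
  per-channel integrated signals are recorded;
* gel images — lanes of 1-D Gaussian bands on a smooth baseline with the
  per-band intensity fractions recorded pre-noise;
* replicate group tables — per-group replicate intensities with
  mean-preserving multiplicative lognormal noise of a stated CV.

All generators are pure functions of (spec, seed): one explicit
``numpy.random.Generator`` stream per call, no global state.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import dilation, disk, erosion

from .exceptions import InvalidSpecError
from .image import FluorescenceImage

__all__ = [
    "CellImageSpec",
    "SyntheticGroundTruth",
    "GelBandSpec",
    "make_cell_image",
    "make_gel_image",
    "make_group_experiment",
]


@dataclass(frozen=True)
class CellImageSpec:
    """Study conditions for one simulated three-channel field of cells.

    Defaults emulate a 512x512 px epifluorescence frame at 200 nm/px
    holding eight well-separated HUVEC-like cells (semi-axes 7 x 5 um,
    nuclei 3.6 x 2.8 um), bright membrane rings and puncta over a low
    flat autofluorescence floor with shot noise.
    """

    frame_shape: tuple[int, int] = (512, 512)
    pixel_size_nm: float = 200.0
    n_cells: int = 8
    cell_axes_nm: tuple[float, float] = (7000.0, 5000.0)
    nucleus_axes_nm: tuple[float, float] = (3600.0, 2800.0)
    surface_ring_intensity: float = 1000.0
    ring_sigma_px: float = 1.5
    internal_puncta_count: int = 20
    internal_puncta_intensity: float = 20000.0
    puncta_sigma_px: float = 1.5
    nuclear_fraction: float = 0.3
    nuclear_intensity: float = 600.0
    background_offset: float = 4.0
    noise_model: str = "poisson"
    gaussian_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0 or self.internal_puncta_count < 0:
            raise InvalidSpecError("counts must be >= 0")
        if not 0.0 <= self.nuclear_fraction <= 1.0:
            raise InvalidSpecError("nuclear_fraction must be in [0, 1]")
        if not self.pixel_size_nm > 0:
            raise InvalidSpecError("pixel_size_nm must be > 0")
        if min(self.cell_axes_nm) <= 0 or min(self.nucleus_axes_nm) <= 0:
            raise InvalidSpecError("axes must be > 0")
        if any(n > c for n, c in zip(self.nucleus_axes_nm, self.cell_axes_nm)):
            raise InvalidSpecError("nucleus must fit inside the cell")
        if self.noise_model not in ("poisson", "gaussian", "none"):
            raise InvalidSpecError("noise_model must be poisson, gaussian or none")
        if min(self.surface_ring_intensity, self.internal_puncta_intensity,
               self.nuclear_intensity, self.background_offset) < 0:
            raise InvalidSpecError("intensities and offset must be >= 0")


@dataclass
class SyntheticGroundTruth:
    """Pre-noise truths recorded alongside each simulated input."""

    true_surface_total: float = 0.0
    true_internal_total: float = 0.0
    true_intranuclear_total: float = 0.0
    per_cell_internal: np.ndarray | None = None
    per_cell_intranuclear: np.ndarray | None = None
    background_offset: float = 0.0
    band_fractions: list[dict[str, float]] | None = None
    lane_bounds: list[tuple[int, int]] | None = None


def _gaussian_stamp(sigma: float) -> np.ndarray:
    """Unit-mass 2-D Gaussian kernel (radius 4 sigma)."""
    radius = max(int(math.ceil(4 * sigma)), 1)
    axis = np.arange(-radius, radius + 1)
    xx, yy = np.meshgrid(axis, axis)
    kernel = np.exp(-(xx**2 + yy**2) / (2 * sigma**2))
    return kernel / kernel.sum()


def _place_centers(spec: CellImageSpec, rng: np.random.Generator,
                   margin: float, min_sep: float) -> np.ndarray:
    centers = []
    lo_r, hi_r = margin, spec.frame_shape[0] - margin
    lo_c, hi_c = margin, spec.frame_shape[1] - margin
    if lo_r >= hi_r or lo_c >= hi_c:
        raise InvalidSpecError("cells do not fit the frame")
    for _ in range(20000):
        if len(centers) == spec.n_cells:
            break
        cand = (rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c))
        if all(math.hypot(cand[0] - r, cand[1] - c) >= min_sep
               for r, c in centers):
            centers.append(cand)
    if len(centers) < spec.n_cells:
        raise InvalidSpecError(
            f"could not place {spec.n_cells} non-overlapping cells in the frame"
        )
    return np.asarray(centers).reshape(-1, 2)


def _apply_noise(channel: np.ndarray, spec: CellImageSpec,
                 rng: np.random.Generator) -> np.ndarray:
    noisy = channel + spec.background_offset
    if spec.noise_model == "poisson":
        return rng.poisson(noisy).astype(float)
    if spec.noise_model == "gaussian":
        noisy = noisy + rng.normal(0.0, spec.gaussian_sigma, noisy.shape)
        return np.clip(noisy, 0.0, None)
    return noisy


def make_cell_image(
    spec: CellImageSpec,
) -> tuple[FluorescenceImage, FluorescenceImage, FluorescenceImage,
           SyntheticGroundTruth]:
    """Render one three-channel field and its ground truth.

    The surface channel carries Gaussian-profile membrane rings; the
    internal channel carries ``internal_puncta_count`` unit-mass Gaussian
    puncta per cell, of which ``round(nuclear_fraction * count)`` are
    placed well inside the nucleus and the rest in the cytoplasm clear of
    the nuclear boundary; the nuclear channel carries the filled nuclear
    ellipses. Identical spec (including seed) gives bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.frame_shape
    a = spec.cell_axes_nm[0] / spec.pixel_size_nm
    b = spec.cell_axes_nm[1] / spec.pixel_size_nm
    na = spec.nucleus_axes_nm[0] / spec.pixel_size_nm
    nb = spec.nucleus_axes_nm[1] / spec.pixel_size_nm

    surface = np.zeros(shape)
    internal = np.zeros(shape)
    nuclear = np.zeros(shape)

    margin = max(a, b) + 8
    centers = (_place_centers(spec, rng, margin, 2 * max(a, b) + 6)
               if spec.n_cells else np.zeros((0, 2)))

    stamp = _gaussian_stamp(spec.puncta_sigma_px)
    stamp_r = stamp.shape[0] // 2
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]]

    n_nuc_puncta = round(spec.nuclear_fraction * spec.internal_puncta_count)
    per_cell_internal = np.zeros(spec.n_cells)
    per_cell_intranuclear = np.zeros(spec.n_cells)

    for i, (cr, cc) in enumerate(centers):
        theta = rng.uniform(0.0, math.pi)
        cos_t, sin_t = math.cos(theta), math.sin(theta)
        dr, dc = rows - cr, cols - cc
        u = dc * cos_t + dr * sin_t
        v = -dc * sin_t + dr * cos_t
        cell_mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        nucleus_mask = (u / na) ** 2 + (v / nb) ** 2 <= 1.0

        # membrane ring: Gaussian falloff of the distance to the cell edge
        d_in = ndi.distance_transform_edt(cell_mask)
        d_out = ndi.distance_transform_edt(~cell_mask)
        d_edge = np.where(cell_mask, d_in, d_out)
        surface += spec.surface_ring_intensity * np.exp(
            -(d_edge**2) / (2 * spec.ring_sigma_px**2)
        )

        nuclear += spec.nuclear_intensity * nucleus_mask

        if spec.internal_puncta_count == 0:
            continue
        nuc_region = erosion(nucleus_mask, disk(6))
        cyto_region = erosion(cell_mask, disk(4)) & ~dilation(
            nucleus_mask, disk(4)
        )
        if not nuc_region.any() or not cyto_region.any():
            raise InvalidSpecError(
                "cell/nucleus too small to place puncta with safety margins"
            )
        nuc_px = np.argwhere(nuc_region)
        cyto_px = np.argwhere(cyto_region)
        for k in range(spec.internal_puncta_count):
            pool = nuc_px if k < n_nuc_puncta else cyto_px
            pr, pc = pool[rng.integers(len(pool))]
            internal[pr - stamp_r:pr + stamp_r + 1,
                     pc - stamp_r:pc + stamp_r + 1] += (
                spec.internal_puncta_intensity * stamp
            )
            per_cell_internal[i] += spec.internal_puncta_intensity
            if k < n_nuc_puncta:
                per_cell_intranuclear[i] += spec.internal_puncta_intensity

    truth = SyntheticGroundTruth(
        true_surface_total=float(surface.sum()),
        true_internal_total=float(internal.sum()),
        true_intranuclear_total=float(per_cell_intranuclear.sum()),
        per_cell_internal=per_cell_internal,
        per_cell_intranuclear=per_cell_intranuclear,
        background_offset=spec.background_offset,
    )

    surface_img = FluorescenceImage(
        _apply_noise(surface, spec, rng), "surface", spec.pixel_size_nm)
    internal_img = FluorescenceImage(
        _apply_noise(internal, spec, rng), "internal", spec.pixel_size_nm)
    nuclear_img = FluorescenceImage(
        _apply_noise(nuclear, spec, rng), "nuclear", spec.pixel_size_nm)
    return surface_img, internal_img, nuclear_img, truth


@dataclass(frozen=True)
class GelBandSpec:
    """One Gaussian band: centre row, sigma (px), integrated mass, role."""

    position: float
    width: float
    integral: float
    role: str = "intact"

    def __post_init__(self) -> None:
        if self.integral < 0 or self.width <= 0:
            raise InvalidSpecError("band integral >= 0 and width > 0 required")


def make_gel_image(
    lanes: list[list[GelBandSpec]],
    image_length: int = 600,
    lane_width: int = 60,
    lane_gap: int = 20,
    margin: int = 30,
    baseline: float = 2.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, SyntheticGroundTruth]:
    """Render gel lanes as 1-D Gaussian band mixtures on a smooth baseline.

    Per-lane band fractions (integrals normalized before noise) and lane
    column bounds are recorded in the ground truth. Bands overlapping
    within a lane trigger a warning; the programmed fractions are still
    recorded.
    """
    n_lanes = len(lanes)
    width = 2 * margin + n_lanes * lane_width + max(n_lanes - 1, 0) * lane_gap
    image = np.zeros((image_length, width))
    rng = np.random.default_rng(seed)
    row_axis = np.arange(image_length, dtype=float)

    lane_bounds: list[tuple[int, int]] = []
    band_fractions: list[dict[str, float]] = []
    for j, bands in enumerate(lanes):
        c0 = margin + j * (lane_width + lane_gap)
        c1 = c0 + lane_width
        lane_bounds.append((c0, c1))
        windows = sorted(
            (band.position - 3 * band.width, band.position + 3 * band.width)
            for band in bands
        )
        if any(b0 < a1 for (_, a1), (b0, _) in zip(windows, windows[1:])):
            warnings.warn(f"overlapping bands in lane {j}", stacklevel=2)
        profile = np.zeros(image_length)
        for band in bands:
            if not 0 <= band.position < image_length:
                raise InvalidSpecError("band position outside the image")
            pdf = np.exp(-((row_axis - band.position) ** 2)
                         / (2 * band.width**2))
            pdf /= pdf.sum()
            profile += band.integral * pdf
        image[:, c0:c1] += profile[:, None] / lane_width
        total = sum(band.integral for band in bands)
        fractions: dict[str, float] = {}
        for band in bands:
            share = band.integral / total if total > 0 else float("nan")
            fractions[band.role] = fractions.get(band.role, 0.0) + share
        band_fractions.append(fractions)

    # gently tilted baseline, removed later by the 1-D opening
    image += baseline * (1.0 + row_axis[:, None] / image_length)
    if noise_sigma > 0:
        image = np.clip(image + rng.normal(0.0, noise_sigma, image.shape),
                        0.0, None)
    truth = SyntheticGroundTruth(
        band_fractions=band_fractions, lane_bounds=lane_bounds
    )
    return image, truth


def make_group_experiment(
    group_means,
    cv: float,
    n_replicates: int = 3,
    seed: int = 0,
    group_names: list[str] | None = None,
) -> pd.DataFrame:
    """Replicate intensity table with multiplicative lognormal noise.

    Each replicate is ``mean * exp(N(-sigma^2/2, sigma))`` with
    ``sigma^2 = ln(1 + cv^2)``, so replicate expectations equal the group
    means at any CV. Returns columns ``group``, ``replicate``, ``value``.
    """
    means = np.asarray(group_means, dtype=float)
    if means.size and means.min() < 0:
        raise InvalidSpecError("group means must be >= 0")
    if cv < 0:
        raise InvalidSpecError("cv must be >= 0")
    if n_replicates < 1:
        raise InvalidSpecError("n_replicates must be >= 1")
    if group_names is None:
        group_names = [f"g{i}" for i in range(means.size)]
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(cv**2))
    rows = []
    for name, mean in zip(group_names, means):
        if cv == 0:
            values = np.full(n_replicates, mean)
        else:
            values = mean * np.exp(
                rng.normal(-sigma**2 / 2, sigma, n_replicates)
            )
        rows.extend(
            {"group": name, "replicate": r, "value": float(val)}
            for r, val in enumerate(values)
        )
    return pd.DataFrame(rows, columns=["group", "replicate", "value"])
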