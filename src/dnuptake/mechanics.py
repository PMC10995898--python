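"""Membrane-wrapping energy budgets for DNA nanostructures (DNs).

The lipid membrane is modelled as a tensionless elastic continuum whose
bending energy follows the Helfrich curvature-elastic form

    E_bend = (kappa / 2) * integral (c1 + c2)^2 dA

with bending modulus ``kappa`` expressed in units of thermal energy (kBT).
For complete engulfment of a particle the membrane adopts the particle's
shape, giving closed forms:

* sphere: ``8 * pi * kappa`` — independent of sphere radius;
* rod (spherocylinder, radius R, tip-to-tip length L): cylindrical body
  ``pi * kappa * (L - 2R) / R`` plus ``8 * pi * kappa`` for the two
  hemispherical end caps;
* flat rectangular tile (w x h, thickness t): the two faces are flat and
  cost nothing; the rim is wrapped as a half-cylinder of radius t/2 swept
  along the perimeter P = 2(w + h), costing ``pi * kappa * P / t``
  (corner Gaussian-curvature contributions are ignored).

Adhesion comes from cholesterol anchors inserting into the bilayer,
``E_adh = n_accessible * x`` kBT where ``x`` is the free-energy gain per
inserted cholesterol. Passive, adhesion-driven wrapping is feasible only
when ``E_adh >= E_bend``; the anchor-count threshold is the smallest n
whose adhesion meets the bending cost.

All energies are in kBT, all lengths in nanometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .exceptions import InvalidGeometryError, InvalidParameterError

__all__ = [
    "Geometry",
    "MembraneModel",
    "AnchorModel",
    "EnergyBudget",
    "bending_energy",
    "adhesion_energy",
    "anchor_threshold",
    "wrapping_feasibility",
    "default_scenarios",
    "DEFAULT_GEOMETRIES",
]

_SHAPE_FIELDS = {
    "sphere": ("sphere_radius",),
    "rod": ("rod_radius", "rod_length"),
    "tile": ("tile_width", "tile_height", "tile_thickness"),
}
_ALL_DIM_FIELDS = tuple(f for fields in _SHAPE_FIELDS.values() for f in fields)

ORIENTATIONS = ("horizontal", "vertical")


@dataclass(frozen=True)
class Geometry:
    """Parametric DN shape with dimensions in nm.

    Exactly the dimension fields of the declared ``shape_kind`` must be set;
    all lengths are strictly positive. ``rod_length`` is tip-to-tip (the
    spherocylinder including its caps), so ``rod_length >= 2 * rod_radius``.
    """

    shape_kind: str
    sphere_radius: float | None = None
    rod_radius: float | None = None
    rod_length: float | None = None
    tile_width: float | None = None
    tile_height: float | None = None
    tile_thickness: float | None = None

    def __post_init__(self) -> None:
        if self.shape_kind not in _SHAPE_FIELDS:
            raise InvalidGeometryError(
                f"unknown shape_kind {self.shape_kind!r}; expected one of "
                f"{sorted(_SHAPE_FIELDS)}"
            )
        required = _SHAPE_FIELDS[self.shape_kind]
        for name in _ALL_DIM_FIELDS:
            value = getattr(self, name)
            if name in required:
                if value is None:
                    raise InvalidGeometryError(
                        f"{self.shape_kind} geometry requires {name}"
                    )
                if not (value > 0 and math.isfinite(value)):
                    raise InvalidGeometryError(f"{name} must be finite and > 0")
            elif value is not None:
                raise InvalidGeometryError(
                    f"{name} must not be set for shape_kind={self.shape_kind!r}"
                )
        if self.shape_kind == "rod" and self.rod_length < 2 * self.rod_radius:
            raise InvalidGeometryError(
                "rod_length is tip-to-tip and must be >= 2 * rod_radius"
            )

    @classmethod
    def sphere(cls, radius: float) -> "Geometry":
        return cls("sphere", sphere_radius=radius)

    @classmethod
    def rod(cls, radius: float, length: float) -> "Geometry":
        return cls("rod", rod_radius=radius, rod_length=length)

    @classmethod
    def tile(cls, width: float, height: float, thickness: float = 2.0) -> "Geometry":
        return cls("tile", tile_width=width, tile_height=height,
                   tile_thickness=thickness)


@dataclass(frozen=True)
class MembraneModel:
    """Membrane elastic parameters; ``kappa`` is the bending modulus in kBT."""

    kappa: float = 25.0

    def __post_init__(self) -> None:
        if not (self.kappa > 0 and math.isfinite(self.kappa)):
            raise InvalidParameterError("kappa must be finite and > 0")


@dataclass(frozen=True)
class AnchorModel:
    """Cholesterol-anchor adhesion parameters.

    ``x_per_anchor`` is the adhesion free-energy gain per inserted
    cholesterol (kBT). ``n_accessible`` counts anchors able to contact the
    membrane in the given orientation; it defaults to ``n_anchors``
    (every anchor reachable — the upper bound on adhesion).
    """

    n_anchors: int
    x_per_anchor: float = 13.0
    orientation: str = "horizontal"
    n_accessible: int | None = None

    def __post_init__(self) -> None:
        if not (self.x_per_anchor > 0 and math.isfinite(self.x_per_anchor)):
            raise InvalidParameterError("x_per_anchor must be finite and > 0")
        if self.n_anchors < 0:
            raise InvalidParameterError("n_anchors must be >= 0")
        if self.orientation not in ORIENTATIONS:
            raise InvalidParameterError(
                f"orientation must be one of {ORIENTATIONS}"
            )
        if self.n_accessible is None:
            object.__setattr__(self, "n_accessible", self.n_anchors)
        if not 0 <= self.n_accessible <= self.n_anchors:
            raise InvalidParameterError(
                "n_accessible must satisfy 0 <= n_accessible <= n_anchors"
            )


@dataclass(frozen=True)
class EnergyBudget:
    """Energy bookkeeping for one wrapping scenario (all energies in kBT)."""

    e_bending: float
    e_adhesion: float
    n_threshold_real: float
    n_threshold_int: int
    feasible: bool


def bending_energy(geometry: Geometry, membrane: MembraneModel) -> float:
    """Helfrich bending cost (kBT) of completely engulfing ``geometry``."""
    kappa = membrane.kappa
    if geometry.shape_kind == "sphere":
        # (kappa/2) (2/R)^2 4 pi R^2 — radius cancels
        return 8.0 * math.pi * kappa
    if geometry.shape_kind == "rod":
        radius = geometry.rod_radius
        body = geometry.rod_length - 2.0 * radius
        return math.pi * kappa * body / radius + 8.0 * math.pi * kappa
    if geometry.shape_kind == "tile":
        perimeter = 2.0 * (geometry.tile_width + geometry.tile_height)
        return math.pi * kappa * perimeter / geometry.tile_thickness
    raise InvalidGeometryError(f"unknown shape_kind {geometry.shape_kind!r}")


def adhesion_energy(anchors: AnchorModel) -> float:
    """Adhesion energy gain (kBT) from membrane-contacting anchors."""
    return anchors.n_accessible * anchors.x_per_anchor


def anchor_threshold(
    geometry: Geometry, membrane: MembraneModel, x_per_anchor: float
) -> tuple[float, int]:
    """Minimum anchor count whose adhesion meets the bending cost.

    Returns ``(n_threshold_real, n_threshold_int)`` where the real threshold
    is ``E_bend / x`` and the integer threshold is its ceiling, with an
    exact-division guard (an integral real threshold is its own ceiling).
    """
    if not (x_per_anchor > 0 and math.isfinite(x_per_anchor)):
        raise InvalidParameterError("x_per_anchor must be finite and > 0")
    e_bend = bending_energy(geometry, membrane)
    n_real = e_bend / x_per_anchor
    nearest = round(n_real)
    if math.isclose(n_real, nearest, rel_tol=1e-9, abs_tol=1e-9):
        n_int = int(nearest)
    else:
        n_int = int(math.ceil(n_real))
    return n_real, max(n_int, 0)


def wrapping_feasibility(
    geometry: Geometry, membrane: MembraneModel, anchors: AnchorModel
) -> EnergyBudget:
    """Assemble the full energy budget and the feasibility verdict.

    Wrapping is feasible when adhesion meets or exceeds the bending cost
    (exact ties count as feasible, up to floating-point round-off).
    """
    e_bend = bending_energy(geometry, membrane)
    e_adh = adhesion_energy(anchors)
    n_real, n_int = anchor_threshold(geometry, membrane, anchors.x_per_anchor)
    feasible = e_adh >= e_bend or math.isclose(e_adh, e_bend, rel_tol=1e-12)
    return EnergyBudget(
        e_bending=e_bend,
        e_adhesion=e_adh,
        n_threshold_real=n_real,
        n_threshold_int=n_int,
        feasible=feasible,
    )


#: Default DN geometries: ~54 nm nanosphere, 7 x 400 nm nanorod,
#: 96 x 74 nm single-layer nanotile.
DEFAULT_GEOMETRIES: dict[str, Geometry] = {
    "sphere": Geometry.sphere(27.0),
    "rod": Geometry.rod(3.5, 400.0),
    "tile": Geometry.tile(96.0, 74.0, 2.0),
}


def default_scenarios(
    kappa: float = 25.0,
    x_per_anchor: float = 13.0,
    anchor_counts: tuple[int, ...] = (4, 10),
) -> pd.DataFrame:
    """Energy budgets for the default DN scenarios.

    Enumerates the three default geometries, both membrane-binding
    orientations for the anisotropic shapes (spheres are orientation-free),
    and the default overhang counts. One row per scenario with the full
    :class:`EnergyBudget` fields.
    """
    membrane = MembraneModel(kappa)
    rows = []
    for shape, geometry in DEFAULT_GEOMETRIES.items():
        orientations = ("horizontal",) if shape == "sphere" else ORIENTATIONS
        for orientation in orientations:
            for n in anchor_counts:
                anchors = AnchorModel(
                    n_anchors=n, x_per_anchor=x_per_anchor, orientation=orientation
                )
                budget = wrapping_feasibility(geometry, membrane, anchors)
                rows.append(
                    {
                        "shape": shape,
                        "orientation": orientation,
                        "n_anchors": n,
                        "n_accessible": anchors.n_accessible,
                        "e_bending": budget.e_bending,
                        "e_adhesion": budget.e_adhesion,
                        "n_threshold_real": budget.n_threshold_real,
                        "n_threshold_int": budget.n_threshold_int,
                        "feasible": budget.feasible,
                    }
                )
    return pd.DataFrame(rows)
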