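"""Tablet geometry: surface area, volume, SA/V ratio, dose, and inverse design.

FDM-printed tablets are idealised as exact solids — a cuboid, a cylinder, a
hollow cylinder (annular tablet) or a right square pyramid.  The surface-area-
to-volume ratio (SA/V, mm^-1) of the printed object is the single geometric
variable that controls release rate in a fixed formulation, so the module
exposes both the forward map (dimensions -> SA, V, SA/V, dose) and the inverse
one (target SA/V, optionally target dose -> dimensions).

All lengths are mm, areas mm^2, volumes mm^3, doses mg.  Surfaces are ideal
geometric surfaces; print-layer roughness is not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

from .exceptions import DomainError, InfeasibleGeometryError, InvalidShapeError

__all__ = [
    "FAMILIES",
    "ShapeSpec",
    "GeometryMetrics",
    "surface_area",
    "volume",
    "sa_over_v",
    "cylinder_sav",
    "dose_from_volume",
    "metrics",
    "solve_dimensions",
]

FAMILIES = ("cuboid", "cylinder", "hollow_cylinder", "square_pyramid")

#: ordered dimension names per family
DIMENSION_NAMES: dict[str, tuple[str, ...]] = {
    "cuboid": ("a", "b", "c"),
    "cylinder": ("r", "h"),
    "hollow_cylinder": ("R", "r", "h"),
    "square_pyramid": ("a", "h"),
}


@dataclass(frozen=True)
class ShapeSpec:
    """A printable tablet shape: family name plus named dimensions in mm.

    Dimension keys per family: cuboid ``a, b, c``; cylinder ``r, h``
    (radius, height); hollow_cylinder ``R, r, h`` (outer radius, inner
    radius, height, with ``r < R``); square_pyramid ``a, h`` (base edge,
    height).
    """

    family: str
    dimensions: Mapping[str, float]

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise InvalidShapeError(
                f"unknown shape family {self.family!r}; expected one of {FAMILIES}"
            )
        expected = set(DIMENSION_NAMES[self.family])
        got = set(self.dimensions)
        if got != expected:
            raise InvalidShapeError(
                f"{self.family} requires dimensions {sorted(expected)}, got {sorted(got)}"
            )
        for name, value in self.dimensions.items():
            if not (value > 0) or not math.isfinite(value):
                raise InvalidShapeError(
                    f"dimension {name}={value} must be a positive finite length (mm)"
                )
        if self.family == "hollow_cylinder" and not (
            self.dimensions["r"] < self.dimensions["R"]
        ):
            raise InvalidShapeError(
                "hollow_cylinder requires inner radius r < outer radius R "
                f"(got r={self.dimensions['r']}, R={self.dimensions['R']})"
            )
        object.__setattr__(self, "dimensions", dict(self.dimensions))

    def __getitem__(self, name: str) -> float:
        return self.dimensions[name]


@dataclass(frozen=True)
class GeometryMetrics:
    """Computed characteristics of one shape (Table-style row)."""

    surface_area: float  # mm^2
    volume: float  # mm^3
    sa_over_v: float  # mm^-1
    dose: float | None = None  # mg


def surface_area(shape: ShapeSpec) -> float:
    """Total external surface area in mm^2 (closed form per family)."""
    d = shape.dimensions
    if shape.family == "cuboid":
        a, b, c = d["a"], d["b"], d["c"]
        return 2.0 * (a * b + a * c + b * c)
    if shape.family == "cylinder":
        r, h = d["r"], d["h"]
        return 2.0 * math.pi * r * (r + h)
    if shape.family == "hollow_cylinder":
        R, r, h = d["R"], d["r"], d["h"]
        # inner + outer lateral walls plus two annular faces
        return 2.0 * math.pi * h * (R + r) + 2.0 * math.pi * (R * R - r * r)
    # right square pyramid: base plus four slanted triangles
    a, h = d["a"], d["h"]
    return a * a + 2.0 * a * math.sqrt(h * h + (a / 2.0) ** 2)


def volume(shape: ShapeSpec) -> float:
    """Enclosed volume in mm^3 (closed form per family)."""
    d = shape.dimensions
    if shape.family == "cuboid":
        return d["a"] * d["b"] * d["c"]
    if shape.family == "cylinder":
        return math.pi * d["r"] ** 2 * d["h"]
    if shape.family == "hollow_cylinder":
        return math.pi * (d["R"] ** 2 - d["r"] ** 2) * d["h"]
    return d["a"] ** 2 * d["h"] / 3.0


def sa_over_v(shape: ShapeSpec) -> float:
    """Surface-area-to-volume ratio in mm^-1."""
    return surface_area(shape) / volume(shape)


def cylinder_sav(r: float, h: float) -> float:
    """Closed-form cylinder SA/V, ``2/r + 2/h`` (useful as an oracle)."""
    if r <= 0 or h <= 0:
        raise InvalidShapeError("cylinder radius and height must be positive")
    return 2.0 / r + 2.0 / h


def dose_from_volume(volume_mm3: float, load_fraction: float, density: float) -> float:
    """API dose in mg of a printed object.

    Parameters
    ----------
    volume_mm3 : object volume in mm^3.
    load_fraction : drug mass fraction of the filament, in (0, 1].
    density : filament density in mg/mm^3.
    """
    if volume_mm3 <= 0:
        raise DomainError(f"volume must be positive, got {volume_mm3}")
    if density <= 0:
        raise DomainError(f"density must be positive, got {density}")
    if not (0.0 < load_fraction <= 1.0):
        raise DomainError(f"load_fraction must lie in (0, 1], got {load_fraction}")
    return volume_mm3 * density * load_fraction


def metrics(
    shape: ShapeSpec,
    load_fraction: float | None = None,
    density: float | None = None,
) -> GeometryMetrics:
    """SA, V, SA/V and (when drug load and density are given) dose."""
    sa = surface_area(shape)
    v = volume(shape)
    dose = None
    if load_fraction is not None and density is not None:
        dose = dose_from_volume(v, load_fraction, density)
    return GeometryMetrics(surface_area=sa, volume=v, sa_over_v=sa / v, dose=dose)


# ---------------------------------------------------------------------------
# inverse design
# ---------------------------------------------------------------------------

def _sav_of(family: str, dims: dict[str, float]) -> float:
    return sa_over_v(ShapeSpec(family, dims))


def _sav_lower_bound(family: str, fixed: Mapping[str, float], free: str) -> float | None:
    """Infimum of attainable SA/V as the free dimension grows, if closed-form.

    For every family SA/V decomposes as (term in the free dimension) plus a
    constant floor set by the fixed dimensions; the floor is the infeasibility
    bound reported to the caller.
    """
    if family == "cuboid":
        others = [v for k, v in fixed.items()]
        return sum(2.0 / v for v in others)
    if family == "cylinder":
        return 2.0 / fixed["r"] if free == "h" else 2.0 / fixed["h"]
    if family == "hollow_cylinder":
        if free == "h":
            return 2.0 / (fixed["R"] - fixed["r"])
        return 2.0 / fixed["h"]
    if family == "square_pyramid" and free == "h":
        return 6.0 / fixed["a"]
    return None


def _solve_free_dim(
    family: str, fixed: Mapping[str, float], free: str, target_sav: float
) -> float:
    """Value of the single free dimension achieving ``target_sav``."""
    # closed forms: cuboid 2/a+2/b+2/c; cylinder 2/r+2/h; hollow 2/(R-r)+2/h
    if family == "cuboid":
        rest = target_sav - sum(2.0 / v for v in fixed.values())
        if rest <= 0:
            raise InfeasibleGeometryError(
                f"cuboid with fixed {dict(fixed)} cannot reach SA/V={target_sav}: "
                f"attainable SA/V > {sum(2.0 / v for v in fixed.values()):.6g} mm^-1",
                bound=sum(2.0 / v for v in fixed.values()),
            )
        return 2.0 / rest
    if family == "cylinder":
        bound = _sav_lower_bound(family, fixed, free)
        rest = target_sav - bound
        if rest <= 0:
            raise InfeasibleGeometryError(
                f"cylinder with fixed {dict(fixed)} cannot reach SA/V={target_sav}: "
                f"attainable SA/V > {bound:.6g} mm^-1 (asymptote 2/{'r' if free == 'h' else 'h'})",
                bound=bound,
            )
        return 2.0 / rest
    if family == "hollow_cylinder" and free == "h":
        bound = 2.0 / (fixed["R"] - fixed["r"])
        rest = target_sav - bound
        if rest <= 0:
            raise InfeasibleGeometryError(
                f"hollow cylinder with fixed {dict(fixed)} cannot reach "
                f"SA/V={target_sav}: attainable SA/V > {bound:.6g} mm^-1 "
                "(asymptote 2/(R-r))",
                bound=bound,
            )
        return 2.0 / rest

    # generic: bracketed root search over the free dimension
    def objective(x: float) -> float:
        dims = dict(fixed)
        dims[free] = x
        try:
            return _sav_of(family, dims) - target_sav
        except InvalidShapeError:
            return math.nan

    grid = np.logspace(-5, 6, 400)
    values = np.array([objective(x) for x in grid])
    ok = np.isfinite(values)
    sign_change = np.nonzero(np.diff(np.sign(values[ok])) != 0)[0]
    if sign_change.size == 0:
        finite = values[ok]
        bound = _sav_lower_bound(family, fixed, free)
        extra = f" (attainable SA/V > {bound:.6g} mm^-1)" if bound is not None else (
            f" (attainable SA/V range on searched bracket: "
            f"[{target_sav + finite.min():.6g}, {target_sav + finite.max():.6g}] mm^-1)"
        )
        raise InfeasibleGeometryError(
            f"{family} with fixed {dict(fixed)} cannot reach SA/V={target_sav}{extra}",
            bound=bound,
        )
    i = sign_change[0]
    lo, hi = grid[ok][i], grid[ok][i + 1]
    return float(brentq(objective, lo, hi, xtol=1e-14, rtol=1e-14))


def _dim_from_volume(
    family: str, dims: dict[str, float], free: str, target_volume: float
) -> float:
    """Closed-form value of ``free`` giving ``target_volume`` with others fixed."""
    if family == "cuboid":
        prod = math.prod(v for k, v in dims.items() if k != free)
        return target_volume / prod
    if family == "cylinder":
        if free == "h":
            return target_volume / (math.pi * dims["r"] ** 2)
        return math.sqrt(target_volume / (math.pi * dims["h"]))
    if family == "hollow_cylinder":
        if free == "h":
            return target_volume / (math.pi * (dims["R"] ** 2 - dims["r"] ** 2))
        if free == "R":
            return math.sqrt(target_volume / (math.pi * dims["h"]) + dims["r"] ** 2)
        inner_sq = dims["R"] ** 2 - target_volume / (math.pi * dims["h"])
        if inner_sq <= 0:
            raise InfeasibleGeometryError(
                "hollow cylinder: requested volume exceeds the full cylinder "
                f"volume pi*R^2*h = {math.pi * dims['R'] ** 2 * dims['h']:.6g} mm^3"
            )
        return math.sqrt(inner_sq)
    # square pyramid V = a^2 h / 3
    if free == "h":
        return 3.0 * target_volume / dims["a"] ** 2
    return math.sqrt(3.0 * target_volume / dims["h"])


def solve_dimensions(
    family: str,
    fixed_dimensions: Mapping[str, float],
    target_sav: float,
    target_dose: float | None = None,
    load_fraction: float | None = None,
    density: float | None = None,
) -> ShapeSpec:
    """Design a shape with a prescribed SA/V ratio (and optionally dose).

    With no dose target exactly one dimension must be left free; it is found
    in closed form where the SA/V decomposes additively (cuboid, cylinder,
    hollow cylinder height) and by bracketed root search otherwise.  With a
    dose target two dimensions must be free: the dose pins the volume
    (``V = dose / (density * load_fraction)``), one free dimension is
    eliminated through the volume constraint and the other is solved for the
    SA/V target.

    Raises
    ------
    InfeasibleGeometryError
        when the target lies below the attainable bound for the fixed
        dimensions (the message names the bound).
    """
    if family not in FAMILIES:
        raise InvalidShapeError(f"unknown shape family {family!r}")
    if target_sav <= 0:
        raise DomainError(f"target SA/V must be positive, got {target_sav}")
    names = DIMENSION_NAMES[family]
    unknown = set(fixed_dimensions) - set(names)
    if unknown:
        raise InvalidShapeError(f"{family} has no dimension(s) {sorted(unknown)}")
    free = [n for n in names if n not in fixed_dimensions]

    if target_dose is None:
        if len(free) != 1:
            raise DomainError(
                f"exactly one free dimension required without a dose target; "
                f"free: {free or 'none'}"
            )
        value = _solve_free_dim(family, fixed_dimensions, free[0], target_sav)
        dims = dict(fixed_dimensions)
        dims[free[0]] = value
        return ShapeSpec(family, dims)

    if load_fraction is None or density is None:
        raise DomainError("a dose target requires load_fraction and density")
    if len(free) != 2:
        raise DomainError(
            f"exactly two free dimensions required with a dose target; free: {free}"
        )
    target_volume = target_dose / (density * load_fraction)
    outer, inner = free

    def objective(x: float) -> float:
        dims = dict(fixed_dimensions)
        dims[outer] = x
        try:
            dims[inner] = _dim_from_volume(family, dims, inner, target_volume)
            return _sav_of(family, dims) - target_sav
        except (InvalidShapeError, InfeasibleGeometryError, ValueError):
            return math.nan

    grid = np.logspace(-5, 6, 400)
    values = np.array([objective(x) for x in grid])
    ok = np.isfinite(values)
    if not ok.any():
        raise InfeasibleGeometryError(
            f"{family}: no geometry matches dose {target_dose} mg at any searched size"
        )
    sign_change = np.nonzero(np.diff(np.sign(values[ok])) != 0)[0]
    if sign_change.size == 0:
        finite = values[ok]
        raise InfeasibleGeometryError(
            f"{family} with volume {target_volume:.6g} mm^3 (dose {target_dose} mg) "
            f"cannot reach SA/V={target_sav}: attainable range "
            f"[{target_sav + finite.min():.6g}, {target_sav + finite.max():.6g}] mm^-1"
        )
    i = sign_change[0]
    grid_ok = grid[ok]
    x = float(brentq(objective, grid_ok[i], grid_ok[i + 1], xtol=1e-14, rtol=1e-14))
    dims = dict(fixed_dimensions)
    dims[outer] = x
    dims[inner] = _dim_from_volume(family, dims, inner, target_volume)
    return ShapeSpec(family, dims)
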