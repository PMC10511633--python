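"""Cell geometry: spherocylinder (cylinder with spherical caps) surface area.

The cell is an ideal cylinder with hemispherical caps, the idealized rod
shape of an E. coli cell.  Two conventions relate volume to area:

``fixed_shape`` (canonical)
    The shape is self-similar: the aspect ratio gamma = total length /
    diameter is constant and the cell scales isotropically.  Then
    A = c(gamma) * V^(2/3) with c(gamma) = 4*pi*gamma * (pi*(2*gamma -
    2/3))^(-2/3); the surface-to-volume ratio vanishes for large cells,
    which is what lets membrane-free compositions approach their
    cytosol-only doubling times at large sizes.

``fixed_radius``
    The radius is constant and the cylinder length varies;
    below the minimal spherocylinder volume (4/3)*pi*r^3 the cell is a
    sphere of whatever radius holds the volume.  A(V) is continuous at the
    regime switch and asymptotically linear in V.
"""

from __future__ import annotations

import math
from typing import NamedTuple

from .parameters import GeometryParams


class ShapeRecord(NamedTuple):
    """Resolved cell dimensions at one operating point (um / um^2 / um^3)."""

    volume_um3: float
    area_um2: float
    radius_um: float
    cylinder_length_um: float  # 0 in the sphere regime
    regime: str  # "spherocylinder" | "sphere"


def cell_dimensions(volume_um3: float, geometry: GeometryParams) -> ShapeRecord:
    """Surface area and resolved dimensions for a given cytoplasmic volume."""
    if volume_um3 <= 0:
        raise ValueError(f"volume must be positive, got {volume_um3}")
    if geometry.mode == "fixed_shape":
        return _fixed_shape(volume_um3, geometry.aspect_ratio)
    return _fixed_radius(volume_um3, geometry.radius_um)


def _fixed_shape(v: float, gamma: float) -> ShapeRecord:
    # V = pi r^3 (2 gamma - 2/3),  A = 4 pi gamma r^2,  Lc = 2 r (gamma - 1)
    q = 2.0 * gamma - 2.0 / 3.0
    r = (v / (math.pi * q)) ** (1.0 / 3.0)
    area = 4.0 * math.pi * gamma * r * r
    lc = 2.0 * r * (gamma - 1.0)
    regime = "sphere" if gamma == 1.0 else "spherocylinder"
    return ShapeRecord(v, area, r, lc, regime)


def _fixed_radius(v: float, r: float) -> ShapeRecord:
    v_sphere = 4.0 / 3.0 * math.pi * r**3
    if v < v_sphere:
        rp = (3.0 * v / (4.0 * math.pi)) ** (1.0 / 3.0)
        return ShapeRecord(v, 4.0 * math.pi * rp * rp, rp, 0.0, "sphere")
    lc = (v - v_sphere) / (math.pi * r * r)
    area = 2.0 * math.pi * r * lc + 4.0 * math.pi * r * r
    return ShapeRecord(v, area, r, lc, "spherocylinder")


def area_um2(volume_um3: float, geometry: GeometryParams) -> float:
    """Shorthand for the surface area at a given volume."""
    return cell_dimensions(volume_um3, geometry).area_um2
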