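"""Axisymmetric two-compartment geometries for phantom and tissue models.

Both domains are cylinders in (r, z) half-plane coordinates with a needle
applicator on the symmetry axis: a metal active tip of radius 0.75 mm and a
plastic trocar shaft of the same radius running from the proximal end of the
tip to the top boundary.  The tissue model adds an optional spherical doped
zone centred on the midpoint of the active tip.

Units are metres everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

__all__ = [
    "Region",
    "GeometryError",
    "Geometry2DAxi",
    "build_geometry",
    "phantom_geometry",
    "tissue_geometry",
    "locate_region",
]


class Region(str, Enum):
    TISSUE = "tissue"
    DOPED = "doped"
    ELECTRODE = "electrode"
    TROCAR = "trocar"


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class Geometry2DAxi:
    """A validated axisymmetric two-compartment domain.

    ``active_span`` is the (z_low, z_high) interval occupied by the metal
    tip; the trocar occupies r <= electrode_radius above it.  A doped zone,
    when present, is the sphere of diameter ``doped_zone_diameter`` centred
    at (r=0, z=doped_zone_center_z).
    """

    kind: str  # "phantom" | "tissue"
    outer_radius: float
    height: float
    electrode_radius: float
    active_span: tuple[float, float]
    doped_zone_diameter: float = 0.0
    doped_zone_center_z: float | None = None
    trocar_present: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("phantom", "tissue"):
            raise GeometryError(f"unknown geometry kind {self.kind!r}")
        for name in ("outer_radius", "height", "electrode_radius"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        z1, z2 = self.active_span
        if not 0.0 < z1 < z2 < self.height:
            raise GeometryError("active_span must lie strictly inside (0, height)")
        if self.electrode_radius >= self.outer_radius:
            raise GeometryError("electrode_radius must be smaller than outer_radius")
        if self.doped_zone_diameter < 0:
            raise GeometryError("doped_zone_diameter must be non-negative")
        if self.doped_zone_diameter > 0:
            zc = self.doped_center_z
            rad = self.doped_zone_diameter / 2.0
            if zc - rad < 0 or zc + rad > self.height or rad > self.outer_radius:
                raise GeometryError("doped zone extends past the domain")

    @property
    def active_length(self) -> float:
        return self.active_span[1] - self.active_span[0]

    @property
    def active_mid_z(self) -> float:
        return 0.5 * (self.active_span[0] + self.active_span[1])

    @property
    def doped_center_z(self) -> float:
        if self.doped_zone_center_z is not None:
            return self.doped_zone_center_z
        return self.active_mid_z

    @property
    def doped_radius(self) -> float:
        return self.doped_zone_diameter / 2.0


def phantom_geometry(
    *,
    outer_radius: float = 0.050,
    height: float = 0.110,
    electrode_radius: float = 0.00075,
    active_span: tuple[float, float] = (0.040, 0.070),
    doped_zone_diameter: float = 0.040,
) -> Geometry2DAxi:
    """The agar-phantom domain: 5-cm radius, 11-cm tall cylinder with a
    4-cm doped sphere centred on the 3-cm active tip (z = 40–70 mm)."""
    return Geometry2DAxi(
        kind="phantom",
        outer_radius=outer_radius,
        height=height,
        electrode_radius=electrode_radius,
        active_span=active_span,
        doped_zone_diameter=doped_zone_diameter,
    )


def tissue_geometry(
    doped_zone_diameter: float = 0.0,
    *,
    outer_radius: float = 0.10,
    height: float = 0.16,
    electrode_radius: float = 0.00075,
    active_length: float = 0.030,
) -> Geometry2DAxi:
    """The liver-tissue domain: 10-cm radius, 16-cm tall cylinder, 3-cm
    active tip centred axially, doped sphere of diameter 0 (non-doped),
    2, 3 or 4 cm centred on the tip midpoint."""
    z_lo = 0.5 * (height - active_length)
    return Geometry2DAxi(
        kind="tissue",
        outer_radius=outer_radius,
        height=height,
        electrode_radius=electrode_radius,
        active_span=(z_lo, z_lo + active_length),
        doped_zone_diameter=doped_zone_diameter,
    )


_TISSUE_ZONES = (0.0, 0.02, 0.03, 0.04)


def build_geometry(spec: dict) -> Geometry2DAxi:
    """Build a validated geometry from a configuration record.

    ``spec`` keys: ``kind`` ("phantom"/"tissue"), optional overrides
    ``r_o``, ``z_0``, ``r_e``, ``active_length`` or ``active_span``, and
    ``doped_zone_diameter`` (for tissue restricted to 0/2/3/4 cm).
    """
    kind = spec.get("kind", "tissue")
    if kind == "phantom":
        kwargs = {}
        if "r_o" in spec:
            kwargs["outer_radius"] = float(spec["r_o"])
        if "z_0" in spec:
            kwargs["height"] = float(spec["z_0"])
        if "r_e" in spec:
            kwargs["electrode_radius"] = float(spec["r_e"])
        if "active_span" in spec:
            kwargs["active_span"] = tuple(spec["active_span"])
        if "doped_zone_diameter" in spec:
            kwargs["doped_zone_diameter"] = float(spec["doped_zone_diameter"])
        return phantom_geometry(**kwargs)
    if kind == "tissue":
        d = float(spec.get("doped_zone_diameter", 0.0))
        if not any(math.isclose(d, v, abs_tol=1e-9) for v in _TISSUE_ZONES):
            raise GeometryError(
                f"tissue doped_zone_diameter must be one of {_TISSUE_ZONES} m, got {d}"
            )
        kwargs = {}
        if "r_o" in spec:
            kwargs["outer_radius"] = float(spec["r_o"])
        if "z_0" in spec:
            kwargs["height"] = float(spec["z_0"])
        if "r_e" in spec:
            kwargs["electrode_radius"] = float(spec["r_e"])
        if "active_length" in spec:
            kwargs["active_length"] = float(spec["active_length"])
        return tissue_geometry(d, **kwargs)
    raise GeometryError(f"unknown geometry kind {kind!r}")


def locate_region(geom: Geometry2DAxi, point: tuple[float, float]) -> Region:
    """Classify a point of the domain into its material region.

    Boundary ties resolve toward the more conductive region (electrode over
    doped over tissue): points exactly on the electrode surface are metal,
    points exactly on the doped-sphere boundary are doped.
    """
    r, z = point
    if r < 0 or r > geom.outer_radius or z < 0 or z > geom.height:
        raise GeometryError(f"point {point} outside domain")
    z1, z2 = geom.active_span
    if r <= geom.electrode_radius:
        if z1 <= z <= z2:
            return Region.ELECTRODE
        if z > z2 and geom.trocar_present:
            return Region.TROCAR
    if geom.doped_zone_diameter > 0:
        d2 = r * r + (z - geom.doped_center_z) ** 2
        if d2 <= geom.doped_radius**2:
            return Region.DOPED
    return Region.TISSUE
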