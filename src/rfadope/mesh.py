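"""Conforming triangular meshes for the axisymmetric domains.

The production mesher builds a tensor-product grid in (r, z), graded
geometrically away from the electrode surface (where current density — and
hence the needed resolution — is highest), snaps grid nodes onto the
doped-sphere interface so region boundaries are conforming polylines, and
splits each quad along its shorter diagonal.  Element regions are assigned
by centroid classification against the exact geometry.

Two auxiliary manufactured-case meshes are provided: a concentric spherical
shell (polar tensor grid, exact boundary representation) used as the
closed-form impedance oracle, and a plain rectangle for thermal oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Geometry2DAxi, Region, locate_region

__all__ = [
    "Mesh",
    "MeshingError",
    "generate_mesh",
    "concentric_shell_mesh",
    "box_mesh",
    "REGION_CODE",
    "CODE_REGION",
]

REGION_CODE = {
    Region.TISSUE: 0,
    Region.DOPED: 1,
    Region.ELECTRODE: 2,
    Region.TROCAR: 3,
}
CODE_REGION = {v: k for k, v in REGION_CODE.items()}


class MeshingError(RuntimeError):
    pass


@dataclass
class Mesh:
    """An axisymmetric triangular mesh with region and boundary tags.

    ``nodes`` is (N, 2) with columns (r, z) in metres; ``tris`` is (M, 3)
    node indices; ``region`` is (M,) integer codes (see ``REGION_CODE``).
    Boolean node masks tag the symmetry axis, the outer (dispersive
    electrode) boundary and the nodes of the active-electrode region.
    """

    nodes: np.ndarray
    tris: np.ndarray
    region: np.ndarray
    on_axis: np.ndarray
    on_outer: np.ndarray
    electrode_nodes: np.ndarray
    _areas: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if np.any(self.nodes[:, 0] < -1e-12):
            raise MeshingError("mesh contains nodes with negative radius")
        a = self.areas
        if np.any(a <= 0):
            raise MeshingError("mesh contains degenerate or inverted elements")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.tris)

    @property
    def areas(self) -> np.ndarray:
        """Signed-positive triangle areas in the (r, z) plane (m²)."""
        if self._areas is None:
            p = self.nodes[self.tris]
            d1 = p[:, 1] - p[:, 0]
            d2 = p[:, 2] - p[:, 0]
            self._areas = 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])
        return self._areas

    @property
    def centroid_r(self) -> np.ndarray:
        return self.nodes[self.tris, 0].mean(axis=1)

    @property
    def element_volumes(self) -> np.ndarray:
        """Solid-of-revolution volume 2π r̄ A of each element (m³)."""
        return 2.0 * np.pi * self.centroid_r * self.areas

    def elements_of(self, region: Region) -> np.ndarray:
        return np.flatnonzero(self.region == REGION_CODE[region])

    def write_vtk(self, path, point_data: dict | None = None, cell_data: dict | None = None) -> None:
        """Write the mesh and fields as a legacy-ASCII VTK unstructured grid."""
        with open(path, "w") as f:
            f.write("# vtk DataFile Version 3.0\nrfadope axisymmetric field\nASCII\n")
            f.write("DATASET UNSTRUCTURED_GRID\n")
            f.write(f"POINTS {self.n_nodes} double\n")
            for r, z in self.nodes:
                f.write(f"{r:.9e} {z:.9e} 0.0\n")
            f.write(f"CELLS {self.n_elements} {4 * self.n_elements}\n")
            for t in self.tris:
                f.write(f"3 {t[0]} {t[1]} {t[2]}\n")
            f.write(f"CELL_TYPES {self.n_elements}\n")
            f.write("5\n" * self.n_elements)
            cell_data = {"region": self.region, **(cell_data or {})}
            f.write(f"CELL_DATA {self.n_elements}\n")
            for name, arr in cell_data.items():
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                f.write("\n".join(f"{v:.9e}" for v in np.asarray(arr, float)))
                f.write("\n")
            if point_data:
                f.write(f"POINT_DATA {self.n_nodes}\n")
                for name, arr in point_data.items():
                    f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    f.write("\n".join(f"{v:.9e}" for v in np.asarray(arr, float)))
                    f.write("\n")


def _graded(a: float, b: float, ha: float, hb: float, hmax: float, q: float = 1.25) -> np.ndarray:
    """Points on [a, b] with geometric grading from spacing ha at a and hb
    at b, both capped at hmax; the step list is rescaled to fit exactly."""
    L = b - a
    if L <= 0:
        raise MeshingError("empty grading interval")
    ha = min(ha, L)
    hb = min(hb, L)
    sa: list[float] = []
    sb: list[float] = []
    ca = cb = 0.0
    h1, h2 = ha, hb
    while ca + cb < L:
        if h1 <= h2:
            sa.append(h1)
            ca += h1
            h1 = min(h1 * q, hmax)
        else:
            sb.append(h2)
            cb += h2
            h2 = min(h2 * q, hmax)
    steps = np.array(sa + sb[::-1])
    steps *= L / steps.sum()
    return a + np.concatenate(([0.0], np.cumsum(steps)))


def _merge_lines(segments: list[tuple[float, float]], hmax: float, q: float = 1.25) -> np.ndarray:
    """Build a full 1D grid from sorted (breakpoint, local spacing) pairs."""
    pts, hs = zip(*segments)
    out = [np.array([pts[0]])]
    for i in range(len(pts) - 1):
        seg = _graded(pts[i], pts[i + 1], hs[i], hs[i + 1], hmax, q)
        out.append(seg[1:])
    return np.concatenate(out)


# (h_min near electrode, h_interface near doped-sphere boundary, h_max far field)
_LEVELS = {
    1: (2.0e-4, 9.0e-4, 6.5e-3),
    2: (1.4e-4, 6.0e-4, 4.5e-3),
    3: (1.0e-4, 4.2e-4, 3.2e-3),
    4: (0.7e-4, 3.0e-4, 2.2e-3),
}


def _dedupe(pairs: list[tuple[float, float]], tol: float = 1e-7) -> list[tuple[float, float]]:
    pairs = sorted(pairs)
    out: list[tuple[float, float]] = []
    for x, h in pairs:
        if out and x - out[-1][0] < tol:
            out[-1] = (out[-1][0], min(out[-1][1], h))
        else:
            out.append((x, h))
    return out


def generate_mesh(geom: Geometry2DAxi, refinement: int = 2) -> Mesh:
    """Generate a locally refined conforming mesh of the domain.

    ``refinement`` 1–4 controls the near-electrode and far-field target
    spacings; node and element counts grow monotonically with the level.
    """
    if refinement not in _LEVELS:
        raise MeshingError(f"refinement level must be one of {sorted(_LEVELS)}")
    h_min, h_if, h_max = _LEVELS[refinement]
    re_, ro = geom.electrode_radius, geom.outer_radius
    z1, z2 = geom.active_span
    R = geom.doped_radius
    zc = geom.doped_center_z

    r_pairs = [(0.0, re_ / 2.0), (re_, h_min), (ro, h_max)]
    z_pairs = [(0.0, h_max), (z1, h_min), (z2, h_min), (geom.height, h_max)]
    if R > 0:
        if re_ < R < ro:
            r_pairs.append((R, h_if))
        z_pairs.extend([(zc - R, h_if), (zc + R, h_if)])
    r_lines = _merge_lines(_dedupe(r_pairs), h_max)
    z_lines = _merge_lines(_dedupe(z_pairs), h_max)

    nr, nz = len(r_lines), len(z_lines)
    rr, zz = np.meshgrid(r_lines, z_lines, indexing="ij")
    nodes = np.column_stack([rr.ravel(), zz.ravel()])

    # local spacing estimate per node (max of adjacent grid steps)
    dr = np.diff(r_lines)
    dz = np.diff(z_lines)
    hr = np.zeros(nr)
    hr[:-1] = dr
    hr[1:] = np.maximum(hr[1:], dr)
    hz = np.zeros(nz)
    hz[:-1] = dz
    hz[1:] = np.maximum(hz[1:], dz)
    h_node = np.minimum.outer(hr, hz).ravel()

    if R > 0:
        nodes = _snap_to_circle(nodes, h_node, geom)

    tris = _triangulate_quads(nodes, nr, nz)
    cent = nodes[tris].mean(axis=1)
    cent[:, 0] = np.maximum(cent[:, 0], 0.0)
    region = np.fromiter(
        (REGION_CODE[locate_region(geom, (r, z))] for r, z in cent),
        dtype=np.int64,
        count=len(tris),
    )

    r, z = nodes[:, 0], nodes[:, 1]
    on_axis = r < 1e-12
    on_outer = (r > ro - 1e-9) | (z < 1e-9) | (z > geom.height - 1e-9)
    elec_nodes = np.zeros(len(nodes), dtype=bool)
    elec = region == REGION_CODE[Region.ELECTRODE]
    elec_nodes[np.unique(tris[elec])] = True
    return Mesh(nodes, tris, region, on_axis, on_outer, elec_nodes)


def _snap_to_circle(nodes: np.ndarray, h_node: np.ndarray, geom: Geometry2DAxi) -> np.ndarray:
    """Project grid nodes close to the doped-sphere boundary onto it.

    Nodes inside twice the electrode radius, or on the domain boundary, are
    left untouched; a greedy minimum-separation guard prevents two snapped
    nodes from collapsing onto nearly the same interface point.
    """
    nodes = nodes.copy()
    R, zc = geom.doped_radius, geom.doped_center_z
    r, z = nodes[:, 0], nodes[:, 1]
    d = np.hypot(r, z - zc)
    movable = (
        (np.abs(d - R) < 0.45 * h_node)
        & ((r > 2.0 * geom.electrode_radius) | (r < 1e-12))
        & (r < geom.outer_radius - 1e-9)
        & (z > 1e-9)
        & (z < geom.height - 1e-9)
        & (d > 1e-12)
    )
    cand = np.flatnonzero(movable)
    cand = cand[np.argsort(np.abs(d[cand] - R))]
    snapped: list[np.ndarray] = []
    for i in cand:
        scale = R / d[i]
        target = np.array([r[i] * scale, zc + (z[i] - zc) * scale])
        if target[0] < 0:
            continue
        sep = 0.5 * h_node[i]
        if any(np.hypot(*(target - s)) < sep for s in snapped):
            continue
        nodes[i] = target
        snapped.append(target)
    return nodes


def _triangulate_quads(nodes: np.ndarray, nr: int, nz: int) -> np.ndarray:
    """Split each grid quad along its shorter diagonal."""
    idx = np.arange(nr * nz).reshape(nr, nz)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    dd = idx[:-1, 1:].ravel()
    diag_ac = np.linalg.norm(nodes[a] - nodes[c], axis=1)
    diag_bd = np.linalg.norm(nodes[b] - nodes[dd], axis=1)
    use_ac = diag_ac <= diag_bd
    t1 = np.where(use_ac[:, None], np.column_stack([a, b, c]), np.column_stack([a, b, dd]))
    t2 = np.where(use_ac[:, None], np.column_stack([a, c, dd]), np.column_stack([b, c, dd]))
    tris = np.vstack([t1, t2])
    # enforce counter-clockwise orientation
    p = nodes[tris]
    twice_area = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 1, 1] - p[:, 0, 1]
    ) * (p[:, 2, 0] - p[:, 0, 0])
    flip = twice_area < 0
    tris[flip, 1], tris[flip, 2] = tris[flip, 2].copy(), tris[flip, 1].copy()
    return tris


def concentric_shell_mesh(
    r_inner: float,
    r_outer: float,
    n_rho: int = 60,
    n_theta: int = 72,
    center_z: float = 0.0,
) -> Mesh:
    """Polar tensor mesh of a spherical shell in the (r, z) half-plane.

    The inner sphere surface is tagged as the electrode (Dirichlet) and the
    outer as the grounded boundary; used for the closed-form series
    resistance oracle Z = (1/4πσ)(1/r_in − 1/r_out).
    """
    rho = r_inner * (r_outer / r_inner) ** np.linspace(0.0, 1.0, n_rho)
    theta = np.linspace(0.0, np.pi, n_theta)
    pr = np.outer(rho, np.sin(theta))
    pz = center_z + np.outer(rho, np.cos(theta))
    nodes = np.column_stack([pr.ravel(), pz.ravel()])
    nodes[:, 0] = np.maximum(nodes[:, 0], 0.0)
    tris = _triangulate_quads(nodes, n_rho, n_theta)
    # drop zero-area slivers on the axis (theta = 0, pi columns collapse there)
    p = nodes[tris]
    d1 = p[:, 1] - p[:, 0]
    d2 = p[:, 2] - p[:, 0]
    area = 0.5 * np.abs(d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])
    keep = area > 1e-18
    tris = tris[keep]
    region = np.zeros(len(tris), dtype=np.int64)
    idx = np.arange(n_rho * n_theta).reshape(n_rho, n_theta)
    elec_nodes = np.zeros(len(nodes), dtype=bool)
    elec_nodes[idx[0, :]] = True
    on_outer = np.zeros(len(nodes), dtype=bool)
    on_outer[idx[-1, :]] = True
    on_axis = nodes[:, 0] < 1e-12
    return Mesh(nodes, tris, region, on_axis, on_outer, elec_nodes)


def box_mesh(
    r0: float, r1: float, z0: float, z1: float, nr: int = 20, nz: int = 20
) -> Mesh:
    """Uniform rectangle mesh (all tissue), for manufactured thermal cases."""
    r_lines = np.linspace(r0, r1, nr)
    z_lines = np.linspace(z0, z1, nz)
    rr, zz = np.meshgrid(r_lines, z_lines, indexing="ij")
    nodes = np.column_stack([rr.ravel(), zz.ravel()])
    tris = _triangulate_quads(nodes, nr, nz)
    region = np.zeros(len(tris), dtype=np.int64)
    on_axis = nodes[:, 0] < 1e-12
    on_outer = (
        (nodes[:, 0] > r1 - 1e-12)
        | (nodes[:, 1] < z0 + 1e-12)
        | (nodes[:, 1] > z1 - 1e-12)
    )
    elec_nodes = np.zeros(len(nodes), dtype=bool)
    return Mesh(nodes, tris, region, on_axis, on_outer, elec_nodes)
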