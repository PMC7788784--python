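"""Axisymmetric P1 finite-element assembly on triangular meshes.

The 3D cylindrically symmetric problems are reduced to the (r, z)
half-plane with a 2πr volume weighting.  Linear (P1) elements are used
throughout; with elementwise-constant coefficients the one-point (centroid)
radial quadrature used for the stiffness matrix and the ring-weighted
lumped mass are exact.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import Mesh

__all__ = ["AxisymP1", "solve_dirichlet", "dirichlet_flux"]


class AxisymP1:
    """Precomputed element geometry and assembly operators for one mesh."""

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        p = mesh.nodes[mesh.tris]  # (M, 3, 2)
        area = mesh.areas
        # gradients of the barycentric basis functions
        r, z = p[..., 0], p[..., 1]
        j, k = [1, 2, 0], [2, 0, 1]
        self.grad_r = (z[:, j] - z[:, k]) / (2.0 * area[:, None])  # (M, 3)
        self.grad_z = (r[:, k] - r[:, j]) / (2.0 * area[:, None])
        self.vol = mesh.element_volumes  # 2π r̄ A
        # ring-weighted nodal integrals ∫ φ_i 2πr dA = 2πA (2r_i+r_j+r_k)/12
        self.w_ring = 2.0 * np.pi * area[:, None] * (2.0 * r + r[:, j] + r[:, k]) / 12.0
        # base stiffness blocks: vol_e * (∇φ_i · ∇φ_j)
        gg = (
            self.grad_r[:, :, None] * self.grad_r[:, None, :]
            + self.grad_z[:, :, None] * self.grad_z[:, None, :]
        )
        self._stiff_base = self.vol[:, None, None] * gg  # (M, 3, 3)
        tri = mesh.tris
        self._rows = np.repeat(tri, 3, axis=1).ravel()
        self._cols = np.tile(tri, (1, 3)).ravel()

    def stiffness(self, coeff_elem: np.ndarray) -> sp.csr_matrix:
        """Assemble ∫ κ ∇u·∇v 2πr dA for an elementwise-constant κ."""
        data = (self._stiff_base * np.asarray(coeff_elem)[:, None, None]).ravel()
        n = self.mesh.n_nodes
        return sp.coo_matrix((data, (self._rows, self._cols)), shape=(n, n)).tocsr()

    def lumped_mass(self, coeff_elem: np.ndarray) -> np.ndarray:
        """Row-sum lumped mass vector for an elementwise-constant coefficient."""
        out = np.zeros(self.mesh.n_nodes)
        np.add.at(out, self.mesh.tris, np.asarray(coeff_elem)[:, None] * self.w_ring)
        return out

    def load(self, q_elem: np.ndarray) -> np.ndarray:
        """Nodal load vector of an elementwise-constant volumetric source."""
        out = np.zeros(self.mesh.n_nodes)
        np.add.at(out, self.mesh.tris, np.asarray(q_elem)[:, None] * self.w_ring)
        return out

    def element_gradient(self, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(∂u/∂r, ∂u/∂z) per element for a nodal field u."""
        uv = u[self.mesh.tris]
        return (uv * self.grad_r).sum(axis=1), (uv * self.grad_z).sum(axis=1)

    def element_mean(self, u: np.ndarray) -> np.ndarray:
        return u[self.mesh.tris].mean(axis=1)


def solve_dirichlet(
    K: sp.csr_matrix,
    rhs: np.ndarray,
    fixed: np.ndarray,
    fixed_values: np.ndarray,
    diag: np.ndarray | None = None,
) -> np.ndarray:
    """Solve (K + diag) u = rhs with values prescribed on ``fixed`` nodes.

    ``diag`` optionally adds a diagonal (lumped-mass) term.  The reduced
    system on the free nodes is solved with a sparse LU factorization.
    """
    n = K.shape[0]
    free = ~fixed
    u = np.zeros(n)
    u[fixed] = fixed_values[fixed]
    A = K if diag is None else K + sp.diags(diag)
    A = A.tocsr()
    rhs_f = rhs[free] - A[free][:, fixed] @ u[fixed]
    A_ff = A[free][:, free].tocsc()
    u[free] = spla.splu(A_ff).solve(rhs_f)
    if not np.all(np.isfinite(u)):
        raise RuntimeError("singular system: no conductive path between electrodes")
    return u


def dirichlet_flux(K: sp.csr_matrix, u: np.ndarray, rhs: np.ndarray, node_mask: np.ndarray) -> float:
    """Discrete flux out of a Dirichlet node set: Σ (K u − rhs) over the set.

    For the potential problem this is the total current leaving the active
    electrode (exactly consistent with the discrete weak form).
    """
    res = K @ u - rhs
    return float(res[node_mask].sum())
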