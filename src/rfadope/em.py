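"""Quasi-static electrical problem: ∇·(σ∇V) = 0, Joule heat and impedance.

At RF frequencies (~500 kHz) conduction currents dominate, so at every
instant the potential obeys the elliptic conduction equation with the
instantaneous conductivity field.  The active electrode is held at the
applied voltage and the dispersive electrode is a V = 0 condition on every
outer boundary; the symmetry axis carries no normal current (natural
boundary condition of the weak form).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fem import AxisymP1, dirichlet_flux, solve_dirichlet
from .mesh import Mesh

__all__ = ["PotentialSolution", "solve_potential", "joule_heat", "impedance"]


@dataclass
class PotentialSolution:
    """Solved potential field with its derived electrical quantities."""

    mesh: Mesh
    v: np.ndarray  # nodal potential (V)
    sigma_elem: np.ndarray  # per-element conductivity (S/m)
    v_applied: float
    current: float  # total current through the active electrode (A)
    power: float  # ∫ σ|∇V|² dV (W)
    q_rf: np.ndarray  # per-element Joule density (W/m³)
    impedance: float  # Z = V/I (voltage-independent by linearity)
    impedance_from_power: float  # Z = V²/P, agrees with V/I by Green's identity


def solve_potential(
    mesh: Mesh,
    sigma_elem: np.ndarray,
    v_applied: float,
    ops: AxisymP1 | None = None,
) -> PotentialSolution:
    """Solve the axisymmetric conduction problem on ``mesh``.

    Dirichlet data: ``v_applied`` on the active-electrode nodes, 0 on the
    outer boundary.  Current is the discrete flux through the electrode node
    set; by Green's identity it agrees with the total dissipated power
    divided by the applied voltage.
    """
    sigma_elem = np.asarray(sigma_elem, dtype=float)
    if np.any(sigma_elem <= 0):
        raise ValueError("sigma must be strictly positive on every element")
    if ops is None:
        ops = AxisymP1(mesh)
    v_applied = float(v_applied)
    v_solve = v_applied if v_applied > 0 else 1.0  # Z is voltage-independent
    K = ops.stiffness(sigma_elem)
    fixed = mesh.electrode_nodes | mesh.on_outer
    vals = np.where(mesh.electrode_nodes, v_solve, 0.0)
    rhs = np.zeros(mesh.n_nodes)
    v = solve_dirichlet(K, rhs, fixed, vals)
    current = dirichlet_flux(K, v, rhs, mesh.electrode_nodes)
    if current <= 0:
        raise RuntimeError("non-positive electrode current")
    gr, gz = ops.element_gradient(v)
    q_rf = sigma_elem * (gr**2 + gz**2)
    power = float((q_rf * ops.vol).sum())
    z_flux = v_solve / current
    z_power = v_solve**2 / power
    scale = v_applied / v_solve
    return PotentialSolution(
        mesh=mesh,
        v=v * scale,
        sigma_elem=sigma_elem,
        v_applied=v_applied,
        current=current * scale,
        power=power * scale**2,
        q_rf=q_rf * scale**2,
        impedance=z_flux,
        impedance_from_power=z_power,
    )


def joule_heat(sol: PotentialSolution) -> np.ndarray:
    """Per-element Joule density Q_RF = σ|∇V|² (W/m³); non-negative."""
    return sol.q_rf


def impedance(sol: PotentialSolution) -> float:
    """Impedance Z = V/I seen between active and dispersive electrodes (Ω)."""
    return sol.impedance
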