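"""Material-property models for RF ablation of dopant-enhanced tissue.

This module collects every constitutive relation the simulator needs:

* reference (37 °C) bulk properties of liver tissue, the metal electrode and
  the insulated plastic trocar;
* the empirical dopant → electrical-conductivity laws for normal saline
  (0.9 % NaCl) and colloidal gold nanoparticle (AuNP, 0.01 wt%) infusion;
* effective-medium mixture rules (linear mixing for density and volumetric
  heat capacity, Maxwell–Eucken for thermal conductivity);
* the exponential temperature dependence of electrical conductivity with an
  irreversible two-orders-of-magnitude desiccation drop across the
  vaporization window;
* the apparent volumetric heat capacity implementing the enthalpy method for
  water vaporization over the 99–100 °C interval.

All temperatures are in °C throughout the package; the Kelvin conversion
happens only inside the Arrhenius damage integrand (see
:mod:`rfadope.damage`).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MaterialProps",
    "DopantKind",
    "DopantSolution",
    "DopedTissueProps",
    "ThermalLawParams",
    "LIVER_TISSUE",
    "METAL_ELECTRODE",
    "PLASTIC_TROCAR",
    "NACL_09PCT",
    "AUNP_COLLOID",
    "sigma_doped_nacl",
    "sigma_doped_aunp",
    "phi_d",
    "density_mixture",
    "volumetric_heat_mixture",
    "k_maxwell_eucken",
    "doped_tissue_props",
    "sigma_of_temperature",
    "apparent_volumetric_heat",
    "write_properties_table",
]


@dataclass(frozen=True)
class MaterialProps:
    """Bulk properties of one material at the 37 °C reference temperature.

    Attributes
    ----------
    rho : float
        Density (kg/m³).
    sigma_ref : float
        Electrical conductivity at 37 °C (S/m).
    c : float
        Specific heat (J/kg·K).
    k : float
        Thermal conductivity (W/m·K).
    """

    rho: float
    sigma_ref: float
    c: float
    k: float

    def __post_init__(self) -> None:
        for name in ("rho", "sigma_ref", "c", "k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"MaterialProps.{name} must be strictly positive")

    @property
    def rho_c(self) -> float:
        """Volumetric heat capacity ρc (J/m³·K)."""
        return self.rho * self.c


#: Healthy liver tissue at 37 °C.
LIVER_TISSUE = MaterialProps(rho=1080.0, sigma_ref=0.2, c=3455.0, k=0.502)
#: Metal of the active electrode (effectively equipotential at 7.4e6 S/m).
METAL_ELECTRODE = MaterialProps(rho=8000.0, sigma_ref=7.4e6, c=480.0, k=18.0)
#: Insulated plastic trocar shaft.
PLASTIC_TROCAR = MaterialProps(rho=70.0, sigma_ref=1e-5, c=1045.0, k=0.026)


class DopantKind(str, Enum):
    NACL = "NaCl_0.9pct"
    AUNP = "AuNP_colloid"


@dataclass(frozen=True)
class DopantSolution:
    """A conductive dopant fluid: normal saline or a gold-nanoparticle colloid.

    ``particle_*`` fields describe the dispersed solid phase and are only
    meaningful for the AuNP colloid; ``particle_diameter`` is metadata (the
    conductivity law is calibrated for 10-nm particles at 500 kHz).
    """

    kind: DopantKind
    solute_mass_fraction: float
    solution_rho: float = 1000.0  # kg/m³
    solution_c: float = 4090.0  # J/kg·K
    solution_k: float = 0.63  # W/m·K
    particle_rho: float = 19300.0  # kg/m³ (gold)
    particle_c: float = 129.0  # J/kg·K
    particle_k: float = 317.0  # W/m·K
    particle_diameter: float = 10e-9  # m, metadata

    def __post_init__(self) -> None:
        if not 0.0 < self.solute_mass_fraction < 1.0:
            raise ValueError("solute_mass_fraction must lie in (0, 1)")


NACL_09PCT = DopantSolution(kind=DopantKind.NACL, solute_mass_fraction=0.009)
AUNP_COLLOID = DopantSolution(kind=DopantKind.AUNP, solute_mass_fraction=0.0001)

# Solid-gold volume fraction per unit infused-colloid volume fraction,
# calibrated so C = 1 % maps to phi_D = 54.15e-9.
_AUNP_PHI_PER_C = 5.415e-6


@dataclass(frozen=True)
class DopedTissueProps:
    """Effective properties of tissue infused with a dopant fluid."""

    concentration_C: float  # volume fraction of dopant fluid in tissue
    phi_D: float  # volume fraction of the dispersed phase
    sigma_ref: float  # S/m at 37 °C
    rho: float  # kg/m³
    rho_c: float  # J/m³·K
    k: float  # W/m·K

    @property
    def c(self) -> float:
        """Specific heat (J/kg·K) implied by rho_c and rho."""
        return self.rho_c / self.rho


@dataclass(frozen=True)
class ThermalLawParams:
    """Parameters of the σ(T) law and the enthalpy (apparent-heat) method.

    ``sigma_temp_coeff`` defaults to 0.015 /°C (a +1.5 %/°C rise of
    conductivity up to 100 °C).  ``desiccation_factor`` multiplies the
    100 °C conductivity once a region has vaporized; desiccation is
    irreversible.  ``latent_volumetric`` is h_fg, the product of the latent
    heat of vaporization of water (2.257e6 J/kg) and the density of water at
    100 °C (958 kg/m³); multiplied by the tissue water content (0.68) it
    gives the apparent volumetric heat capacity on the 99–100 °C plateau.
    ``post_vapor_rho_c`` (ρ_g c_g) defaults to the liquid-phase value of
    tissue as a continuation; its influence is small because conductivity is
    desiccated above 100 °C.
    """

    sigma_temp_coeff: float = 0.015  # 1/°C
    sigma_temp_model: str = "exponential"  # or "linear": 1 + coeff·(T − T_ref)
    T_ref: float = 37.0  # °C
    desiccation_factor: float = 0.01
    vaporization_window: tuple[float, float] = (99.0, 100.0)  # °C
    latent_volumetric: float = 2.257e6 * 958.0  # h_fg, J/m³
    water_content_C: float = 0.68
    post_vapor_rho_c: float | None = None  # J/m³·K; None → continue ρ_l c_l

    def __post_init__(self) -> None:
        if not 0.0 < self.desiccation_factor < 1.0:
            raise ValueError("desiccation_factor must lie in (0, 1)")
        if not 0.0 < self.water_content_C < 1.0:
            raise ValueError("water_content_C must lie in (0, 1)")


DEFAULT_THERMAL_LAW = ThermalLawParams()


def sigma_doped_nacl(concentration_C: float, sigma_S: float) -> float:
    """Conductivity of a substrate infused with normal saline.

    The empirical law for agar substrates relates conductivity linearly to
    grams of NaCl per mL of solution with slope 215 (S/m)/(g/mL).  Infusing
    a volume fraction ``concentration_C`` of 0.9 % NaCl contributes
    ``0.009 * concentration_C`` g/mL, on top of the non-doped substrate
    conductivity ``sigma_S``.

    Parameters
    ----------
    concentration_C : float
        Volume fraction of saline in the doped region, in [0, 1].
    sigma_S : float
        Conductivity of the non-doped substrate (S/m), > 0.
    """
    if not 0.0 <= concentration_C <= 1.0:
        raise ValueError("concentration_C must lie in [0, 1]")
    if sigma_S <= 0:
        raise ValueError("sigma_S must be positive")
    return sigma_S + 215.0 * (0.009 * concentration_C)


def sigma_doped_aunp(concentration_wt_pct: float, sigma_S: float) -> float:
    """Conductivity of a substrate doped with 0.01 wt% AuNP colloid.

    Linear in the weight-percent concentration with slope 0.071 (S/m)/wt%,
    calibrated on agar phantoms at 500 kHz with 10-nm particles.
    """
    if not 0.0 <= concentration_wt_pct <= 10.0:
        raise ValueError("concentration_wt_pct must lie in [0, 10]")
    if sigma_S <= 0:
        raise ValueError("sigma_S must be positive")
    return 0.071 * concentration_wt_pct + sigma_S


def phi_d(
    dopant: DopantSolution,
    concentration_C: float,
    *,
    first_principles: bool = False,
) -> float:
    """Volume fraction of the dispersed dopant phase in the doped tissue.

    For saline the dispersed phase is the whole solution, so phi_D equals the
    infused volume fraction.  For the AuNP colloid only the solid gold
    counts; the default constant (5.415e-6 per unit C) is calibrated to the
    tabulated value 54.15e-9 at C = 1 %.  ``first_principles=True`` instead
    derives the fraction from the colloid's solute mass fraction and the
    densities of the colloid and of gold.
    """
    if concentration_C < 0:
        raise ValueError("concentration_C must be non-negative")
    if dopant.kind is DopantKind.NACL:
        return concentration_C
    if first_principles:
        per_c = dopant.solute_mass_fraction * dopant.solution_rho / dopant.particle_rho
        return concentration_C * per_c
    return concentration_C * _AUNP_PHI_PER_C


def density_mixture(rho_tissue: float, rho_D: float, phi_D: float) -> float:
    """Linear volume-fraction mixture of densities."""
    if not 0.0 <= phi_D <= 1.0:
        raise ValueError("phi_D must lie in [0, 1]")
    return (1.0 - phi_D) * rho_tissue + phi_D * rho_D


def volumetric_heat_mixture(rho_c_tissue: float, rho_c_D: float, phi_D: float) -> float:
    """Linear volume-fraction mixture of volumetric heat capacities."""
    if not 0.0 <= phi_D <= 1.0:
        raise ValueError("phi_D must lie in [0, 1]")
    return (1.0 - phi_D) * rho_c_tissue + phi_D * rho_c_D


def k_maxwell_eucken(k_tissue: float, k_D: float, phi_D: float) -> float:
    """Maxwell–Eucken effective thermal conductivity of a dilute suspension.

    ``k_tissue`` is the continuous phase, ``k_D`` the dispersed particles at
    volume fraction ``phi_D`` in [0, 1).
    """
    if not 0.0 <= phi_D < 1.0:
        raise ValueError("phi_D must lie in [0, 1)")
    if k_tissue <= 0 or k_D <= 0:
        raise ValueError("conductivities must be positive")
    num = k_D + 2.0 * k_tissue - 2.0 * phi_D * (k_tissue - k_D)
    den = k_D + 2.0 * k_tissue + phi_D * (k_tissue - k_D)
    return k_tissue * num / den


def doped_tissue_props(
    base: MaterialProps,
    dopant: DopantSolution,
    concentration: float,
    *,
    first_principles_phi: bool = False,
) -> DopedTissueProps:
    """Effective properties of tissue doped at a given concentration.

    ``concentration`` is the volume fraction (0–0.10) of dopant fluid in the
    doped region; for the AuNP colloid this same number, expressed in
    percent, enters the weight-percent conductivity law (the sweep labels
    1–10 % are used interchangeably in both roles).
    """
    if not 0.0 <= concentration <= 0.10 + 1e-12:
        raise ValueError("concentration must lie in [0, 0.10]")
    if concentration == 0.0:
        return DopedTissueProps(
            concentration_C=0.0,
            phi_D=0.0,
            sigma_ref=base.sigma_ref,
            rho=base.rho,
            rho_c=base.rho_c,
            k=base.k,
        )
    phi = phi_d(dopant, concentration, first_principles=first_principles_phi)
    if dopant.kind is DopantKind.NACL:
        # saline: density, heat capacity and thermal conductivity are so
        # close to tissue that the thermal columns stay at tissue values
        sigma = sigma_doped_nacl(concentration, base.sigma_ref)
        rho, rho_c, k = base.rho, base.rho_c, base.k
    elif dopant.kind is DopantKind.AUNP:
        # gold particles: mixture rules with the (tiny) solid-phase fraction
        sigma = sigma_doped_aunp(concentration * 100.0, base.sigma_ref)
        rho = density_mixture(base.rho, dopant.particle_rho, phi)
        rho_c = volumetric_heat_mixture(
            base.rho_c, dopant.particle_rho * dopant.particle_c, phi
        )
        k = k_maxwell_eucken(base.k, dopant.particle_k, phi)
    else:  # pragma: no cover - enum exhausts kinds
        raise ValueError(f"unknown dopant kind {dopant.kind!r}")
    return DopedTissueProps(
        concentration_C=concentration,
        phi_D=phi,
        sigma_ref=sigma,
        rho=rho,
        rho_c=rho_c,
        k=k,
    )


def sigma_of_temperature(
    sigma_ref: float | np.ndarray,
    T: float | np.ndarray,
    params: ThermalLawParams = DEFAULT_THERMAL_LAW,
    *,
    T_peak: float | np.ndarray | None = None,
) -> float | np.ndarray:
    """Electrical conductivity at temperature ``T`` (°C).

    Exponential rise ``sigma_ref * exp(coeff*(T - T_ref))`` up to the onset
    of vaporization (99 °C); across the 99–100 °C vaporization window the
    conductivity falls linearly by two orders of magnitude (progressive
    desiccation while the latent heat is absorbed), and stays at the
    desiccated value above 100 °C.  Desiccation is irreversible: passing
    ``T_peak`` (the running maximum temperature) keeps the drop in place
    even if ``T`` later falls.
    """
    T = np.asarray(T, dtype=float)
    lo, hi = params.vaporization_window
    T_dess = T if T_peak is None else np.maximum(T, np.asarray(T_peak, dtype=float))
    coeff = params.sigma_temp_coeff
    f = params.desiccation_factor
    dT = np.minimum(T, lo) - params.T_ref
    if params.sigma_temp_model == "linear":
        sigma_wet = sigma_ref * np.maximum(1.0 + coeff * dT, 1e-6)
    else:
        sigma_wet = sigma_ref * np.exp(coeff * dT)
    frac = np.clip((T_dess - lo) / (hi - lo), 0.0, 1.0)
    out = sigma_wet * (1.0 + (f - 1.0) * frac)
    return float(out) if out.ndim == 0 else out


def apparent_volumetric_heat(
    T: float | np.ndarray,
    material_rho_c: float | np.ndarray,
    params: ThermalLawParams = DEFAULT_THERMAL_LAW,
) -> float | np.ndarray:
    """Apparent volumetric heat capacity ∂(ρh)/∂T (J/m³·K) at ``T`` (°C).

    Enthalpy method: the liquid-phase ρc below 99 °C, the latent plateau
    ``h_fg * water_content`` on (99, 100], and the post-vaporization ρ_g c_g
    above 100 °C.
    """
    T = np.asarray(T, dtype=float)
    lo, hi = params.vaporization_window
    plateau = params.latent_volumetric * params.water_content_C
    post = params.post_vapor_rho_c
    rho_c_g = material_rho_c if post is None else post
    out = np.where(
        T <= lo, material_rho_c, np.where(T <= hi, plateau, rho_c_g)
    )
    return float(out) if out.ndim == 0 else out


def enthalpy_density(
    T: float | np.ndarray,
    material_rho_c: float | np.ndarray,
    params: ThermalLawParams = DEFAULT_THERMAL_LAW,
    *,
    T_zero: float = 0.0,
) -> float | np.ndarray:
    """Volumetric enthalpy ρh (J/m³) relative to ``T_zero``.

    Piecewise-linear integral of :func:`apparent_volumetric_heat`; the
    secant of this function drives the nonlinear thermal step so that a node
    crossing the 99–100 °C window absorbs exactly ``h_fg * C`` per unit
    volume.
    """
    T = np.asarray(T, dtype=float)
    lo, hi = params.vaporization_window
    plateau = params.latent_volumetric * params.water_content_C
    post = params.post_vapor_rho_c
    rho_c_g = material_rho_c if post is None else post
    h_lo = material_rho_c * (lo - T_zero)
    h_hi = h_lo + plateau * (hi - lo)
    out = np.where(
        T <= lo,
        material_rho_c * (T - T_zero),
        np.where(T <= hi, h_lo + plateau * (T - lo), h_hi + rho_c_g * (T - hi)),
    )
    return float(out) if out.ndim == 0 else out


def write_properties_table(path: str | Path, sigma_S: float = LIVER_TISSUE.sigma_ref) -> pd.DataFrame:
    """Write the doped-tissue property table (plus base materials) as CSV.

    Columns: material, C_pct, phi_D, sigma_S_per_m, c_J_per_kgK, k_W_per_mK.
    Returns the DataFrame written.
    """
    rows = []
    for name, mat in (
        ("healthy_tissue", LIVER_TISSUE),
        ("metal_electrode", METAL_ELECTRODE),
        ("plastic_trocar", PLASTIC_TROCAR),
    ):
        rows.append((name, 0.0, 0.0, mat.sigma_ref, mat.c, mat.k))
    for label, dopant in (("NaCl_0.9pct", NACL_09PCT), ("AuNP_0.01wt", AUNP_COLLOID)):
        for pct in (1, 2, 5, 10):
            p = doped_tissue_props(LIVER_TISSUE, dopant, pct / 100.0)
            rows.append((f"tissue+{label}", float(pct), p.phi_D, p.sigma_ref, p.c, p.k))
    df = pd.DataFrame(
        rows,
        columns=["material", "C_pct", "phi_D", "sigma_S_per_m", "c_J_per_kgK", "k_W_per_mK"],
    )
    df.to_csv(path, index=False)
    return df
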