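"""Material-property laws: dopant conductivity, mixtures, σ(T), enthalpy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rfadope.properties import (
    AUNP_COLLOID,
    DEFAULT_THERMAL_LAW,
    LIVER_TISSUE,
    NACL_09PCT,
    ThermalLawParams,
    apparent_volumetric_heat,
    density_mixture,
    doped_tissue_props,
    enthalpy_density,
    k_maxwell_eucken,
    phi_d,
    sigma_doped_aunp,
    sigma_doped_nacl,
    sigma_of_temperature,
    volumetric_heat_mixture,
    write_properties_table,
)


class TestDopantConductivity:
    @pytest.mark.parametrize(
        "conc, sigma_s, expected",
        [(0.10, 0.2, 0.3935), (0.0, 0.2, 0.2), (0.01, 0.2, 0.21935)],
    )
    def test_nacl_law(self, conc, sigma_s, expected):
        assert sigma_doped_nacl(conc, sigma_s) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "wt, sigma_s, expected",
        [(1.0, 0.067, 0.138), (0.0, 0.2, 0.2), (10.0, 0.2, 0.910)],
    )
    def test_aunp_law(self, wt, sigma_s, expected):
        assert sigma_doped_aunp(wt, sigma_s) == pytest.approx(expected, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            sigma_doped_nacl(-0.1, 0.2)
        with pytest.raises(ValueError):
            sigma_doped_nacl(1.5, 0.2)
        with pytest.raises(ValueError):
            sigma_doped_aunp(-1.0, 0.2)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 0.99))
    @settings(max_examples=50, deadline=None)
    def test_affine_increasing(self, c1, frac):
        """Both laws are affine and strictly increasing in concentration."""
        c0 = c1 * frac
        lo, hi = sigma_doped_nacl(c0, 0.2), sigma_doped_nacl(c1, 0.2)
        assert hi >= lo
        mid = sigma_doped_nacl(0.5 * (c0 + c1), 0.2)
        assert mid == pytest.approx(0.5 * (lo + hi), rel=1e-12)


class TestPhiD:
    def test_aunp_calibration(self):
        assert phi_d(AUNP_COLLOID, 0.01) == pytest.approx(54.15e-9, rel=1e-9)
        assert phi_d(AUNP_COLLOID, 0.10) == pytest.approx(541.50e-9, rel=1e-9)

    def test_zero_and_nacl(self):
        assert phi_d(AUNP_COLLOID, 0.0) == 0.0
        assert phi_d(NACL_09PCT, 0.05) == 0.05

    def test_first_principles_close_to_calibrated(self):
        fp = phi_d(AUNP_COLLOID, 0.01, first_principles=True)
        assert fp == pytest.approx(51.8e-9, rel=0.01)


class TestMixtures:
    def test_density_examples(self):
        assert density_mixture(1080, 19300, 0) == 1080
        assert density_mixture(1080, 19300, 541.5e-9) == pytest.approx(1080.0099, abs=1e-3)
        assert density_mixture(1080, 1000, 0.10) == pytest.approx(1072.0)

    def test_volumetric_heat_examples(self):
        assert volumetric_heat_mixture(3.7314e6, 4.09e6, 0) == 3.7314e6
        assert volumetric_heat_mixture(3.7314e6, 4.09e6, 0.10) == pytest.approx(
            3.767e6, rel=1e-3
        )

    def test_maxwell_eucken_identity_and_limits(self):
        assert k_maxwell_eucken(0.502, 317, 0) == pytest.approx(0.502)
        assert k_maxwell_eucken(0.502, 0.502, 0.3) == pytest.approx(0.502)
        assert k_maxwell_eucken(0.502, 317, 541.5e-9) == pytest.approx(0.502, abs=5e-4)

    @given(
        st.floats(0.1, 5.0), st.floats(0.1, 400.0), st.floats(0.0, 0.99)
    )
    @settings(max_examples=100, deadline=None)
    def test_maxwell_eucken_bounds(self, k_t, k_d, phi):
        """Effective conductivity lies between the two phase conductivities."""
        k_eff = k_maxwell_eucken(k_t, k_d, phi)
        assert min(k_t, k_d) - 1e-12 <= k_eff <= max(k_t, k_d) + 1e-12

    def test_zero_fraction_bit_for_bit(self):
        assert density_mixture(1080.0, 19300.0, 0.0) == 1080.0
        assert volumetric_heat_mixture(3.7314e6, 1.0, 0.0) == 3.7314e6
        assert k_maxwell_eucken(0.502, 317.0, 0.0) == 0.502


class TestDopedTissueTable:
    """The composed doped-tissue properties reproduce the published table."""

    NACL_SIGMA = {1: 0.219, 2: 0.238, 5: 0.297, 10: 0.394}
    AUNP_SIGMA = {1: 0.271, 2: 0.342, 5: 0.555, 10: 0.910}
    AUNP_PHI = {1: 54.15e-9, 2: 108.30e-9, 5: 270.75e-9, 10: 541.50e-9}

    @pytest.mark.parametrize("pct", [1, 2, 5, 10])
    def test_nacl_rows(self, pct):
        p = doped_tissue_props(LIVER_TISSUE, NACL_09PCT, pct / 100.0)
        assert p.sigma_ref == pytest.approx(self.NACL_SIGMA[pct], abs=1.01e-3)
        assert p.c == pytest.approx(3455, abs=0.5)
        assert p.k == pytest.approx(0.502, abs=5e-4)

    @pytest.mark.parametrize("pct", [1, 2, 5, 10])
    def test_aunp_rows(self, pct):
        p = doped_tissue_props(LIVER_TISSUE, AUNP_COLLOID, pct / 100.0)
        assert p.sigma_ref == pytest.approx(self.AUNP_SIGMA[pct], abs=1e-3)
        assert p.phi_D == pytest.approx(self.AUNP_PHI[pct], rel=1e-6)
        assert p.c == pytest.approx(3455, abs=0.5)
        assert p.k == pytest.approx(0.502, abs=5e-4)

    def test_non_doped_limit(self):
        p = doped_tissue_props(LIVER_TISSUE, NACL_09PCT, 0.0)
        assert (p.sigma_ref, p.rho, p.k) == (0.2, 1080.0, 0.502)

    def test_table_writer(self, tmp_path):
        df = write_properties_table(tmp_path / "props.csv")
        assert (tmp_path / "props.csv").exists()
        assert len(df) == 11  # 3 base materials + 8 doped rows
        assert set(df.columns) >= {"material", "C_pct", "sigma_S_per_m"}


class TestSigmaOfTemperature:
    def test_reference_and_rise(self):
        assert sigma_of_temperature(0.2, 37.0) == pytest.approx(0.2)
        assert sigma_of_temperature(0.2, 47.0) == pytest.approx(0.2 * np.e**0.15)

    def test_desiccated_value(self):
        """Above the window the 99 °C value is scaled by the desiccation factor."""
        hot = sigma_of_temperature(0.2, 105.0)
        wet99 = 0.2 * np.exp(0.015 * (99.0 - 37.0))
        assert hot == pytest.approx(0.01 * wet99, rel=1e-12)

    def test_continuity_across_window(self):
        lo = sigma_of_temperature(0.2, 99.0 - 1e-9)
        mid = sigma_of_temperature(0.2, 99.0 + 1e-9)
        hi = sigma_of_temperature(0.2, 100.0 - 1e-9)
        dry = sigma_of_temperature(0.2, 100.0 + 1e-9)
        assert mid == pytest.approx(lo, rel=1e-6)
        assert dry == pytest.approx(hi, rel=1e-4)

    def test_peak_latch_irreversible(self):
        """A region that vaporized stays desiccated when it cools."""
        cooled = sigma_of_temperature(0.2, 60.0, T_peak=105.0)
        never_hot = sigma_of_temperature(0.2, 60.0)
        assert cooled == pytest.approx(0.01 * never_hot, rel=1e-12)


class TestApparentHeat:
    def test_branches(self):
        law = DEFAULT_THERMAL_LAW
        assert apparent_volumetric_heat(50.0, 3.7314e6, law) == 3.7314e6
        plateau = apparent_volumetric_heat(99.5, 3.7314e6, law)
        assert plateau == pytest.approx(0.68 * 2.257e6 * 958.0, rel=1e-12)
        assert plateau == pytest.approx(1.470e9, rel=1e-3)

    def test_first_branch_temperature_independent(self):
        vals = apparent_volumetric_heat(np.linspace(37, 99, 30), 3.7314e6)
        assert np.all(vals == 3.7314e6)

    def test_enthalpy_latent_jump(self):
        """Crossing the window costs exactly h_fg·C per unit volume."""
        law = DEFAULT_THERMAL_LAW
        dh = enthalpy_density(100.0, 3.7314e6, law) - enthalpy_density(
            99.0, 3.7314e6, law
        )
        assert dh == pytest.approx(law.latent_volumetric * law.water_content_C)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ThermalLawParams(desiccation_factor=0.0)
        with pytest.raises(ValueError):
            ThermalLawParams(water_content_C=1.5)
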