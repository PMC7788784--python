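"""Transient enthalpy solver, roll-off detection and protocol behavior."""

import numpy as np
import pytest

from rfadope.geometry import tissue_geometry
from rfadope.mesh import box_mesh
from rfadope.thermal import (
    CoupledModel,
    ProtocolSpec,
    RolloffConfigurationError,
    detect_rolloff,
    run_protocol,
    step_temperature,
)


def _insulated_model(nr=10, nz=10, protocol=None):
    m = box_mesh(0.01, 0.02, 0.0, 0.01, nr, nz)
    m.on_outer[:] = False
    proto = protocol or ProtocolSpec(v_applied=0.0, time_step=1.0)
    return CoupledModel(tissue_geometry(0.0), None, proto, mesh=m)


class TestDetectRolloff:
    def test_linear_interpolation(self):
        t = detect_rolloff([0.0, 10.0, 20.0], [80.0, 90.0, 110.0], 100.0)
        assert t == pytest.approx(15.0)

    def test_never_crossed(self):
        assert detect_rolloff([0.0, 10.0], [80.0, 90.0], 100.0) is None

    def test_initially_at_threshold_is_config_error(self):
        with pytest.raises(RolloffConfigurationError):
            detect_rolloff([0.0, 10.0], [100.0, 120.0], 100.0)

    def test_empty_trace(self):
        with pytest.raises(ValueError):
            detect_rolloff([], [], 100.0)


class TestThermalStep:
    def test_equilibrium_without_source(self):
        model = _insulated_model()
        q = np.zeros(model.mesh.n_elements)
        for _ in range(5):
            step_temperature(model, 1.0, q)
        assert np.allclose(model.state.T, 37.0, atol=1e-10)

    def test_uniform_source_linear_rise(self):
        """Insulated uniform heating: dT/dt = q/(ρc) = 0.01 °C/s."""
        model = _insulated_model()
        q = np.full(model.mesh.n_elements, 3.7314e4)
        for _ in range(20):
            step_temperature(model, 1.0, q)
        assert np.allclose(model.state.T, 37.0 + 20 * 0.01, atol=1e-8)

    def test_latent_plateau_energy_bookkeeping(self):
        """Crossing 99→100 °C absorbs h_fg·C per unit volume."""
        model = _insulated_model()
        law = model.law
        q_val = 3.7314e6  # 1 °C/s below the window
        q = np.full(model.mesh.n_elements, q_val)
        for _ in range(62):  # reach exactly 99 °C
            step_temperature(model, 1.0, q)
        assert np.allclose(model.state.T, 99.0, atol=1e-6)
        plateau_s = law.latent_volumetric * law.water_content_C / q_val
        n_full = int(plateau_s)
        for _ in range(n_full):
            step_temperature(model, 1.0, q)
        # still inside the window (up to the Newton convergence tolerance)
        assert np.all(model.state.T <= 100.0 + 0.05)
        for _ in range(20):
            step_temperature(model, 1.0, q)
        # total energy in minus sensible heat equals the latent term
        sensible = (model.state.T.mean() - 37.0 - 1.0) * 3.7314e6
        latent = (62 + n_full + 20) * q_val - sensible
        assert latent == pytest.approx(law.latent_volumetric * law.water_content_C, rel=5e-3)

    def test_invalid_dt(self):
        model = _insulated_model()
        with pytest.raises(ValueError):
            step_temperature(model, -1.0, np.zeros(model.mesh.n_elements))


class TestEnergyConservation:
    def test_delivered_energy_accounted(self):
        """Electrical energy in = enthalpy change + boundary losses (±2%)."""
        geom = tissue_geometry(0.0)
        proto = ProtocolSpec(v_applied=70.0, time_step=0.5, max_duration=30.0)
        model = CoupledModel(geom, None, proto, refinement=1)
        h0 = model._enthalpy(model.state.T).sum()
        e_in = 0.0
        loss = 0.0
        for _ in range(40):
            sol = model.solve_em()
            T_before = model.state.T.copy()
            model.step_thermal(proto.time_step, sol.q_rf)
            e_in += sol.power * proto.time_step
            # boundary flux: thermal-system residual at the fixed nodes
            F = model.ops.load(sol.q_rf) + model._F_cool
            res = (
                model._enthalpy(model.state.T)
                - model._enthalpy(T_before)
                + proto.time_step * (model.K_tot @ model.state.T - F)
            )
            loss += -res[model.fixed].sum()
        dh = model._enthalpy(model.state.T).sum() - h0
        assert dh + loss == pytest.approx(e_in, rel=0.02)


class TestRunProtocol:
    def test_zero_voltage_never_rolls_off(self):
        res = run_protocol(
            tissue_geometry(0.0),
            None,
            ProtocolSpec(v_applied=0.0, time_step=0.5, max_duration=2.0),
            refinement=1,
        )
        assert res.t_rolloff is None
        # no Joule heating; only the electrode pre-cooling perturbs Z slightly
        assert res.impedance == pytest.approx(res.initial_impedance, rel=0.10)
        assert res.energy_J == pytest.approx(0.0)

    def test_threshold_below_initial_impedance_rejected(self):
        with pytest.raises(RolloffConfigurationError):
            run_protocol(
                tissue_geometry(0.0),
                None,
                ProtocolSpec(
                    v_applied=50.0,
                    time_step=0.5,
                    max_duration=2.0,
                    rolloff_threshold=50.0,
                ),
                refinement=1,
            )

    def test_rolloff_run_invariants(self, run_nd_90v):
        """Roll-off crossed the threshold; fields bounded; damage monotone."""
        res = run_nd_90v
        assert res.t_rolloff is not None
        assert res.impedance[-1] >= 100.0
        assert res.impedance[0] < 100.0
        assert res.T_final.max() < 300.0
        assert res.T_final.min() >= 8.0 - 1e-6
        assert np.all(res.omega_final >= 0.0)
        # energy trace consistent with the power trace
        assert res.energy_J == pytest.approx(
            np.sum(res.power[:-1] * np.diff(res.times)), rel=1e-6
        )

    def test_temporal_convergence_of_rolloff(self):
        """Halving the time step moves the roll-off time by < 2%."""
        t = {}
        for dt in (0.125, 0.0625):
            res = run_protocol(
                tissue_geometry(0.0),
                None,
                ProtocolSpec(v_applied=90.0, time_step=dt, max_duration=300.0),
                refinement=3,
            )
            t[dt] = res.t_rolloff
        assert abs(t[0.0625] / t[0.125] - 1.0) < 0.02

    def test_desiccation_latch_never_resets(self, run_nd_90v):
        assert run_nd_90v.impedance[-1] > run_nd_90v.impedance[-2]
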