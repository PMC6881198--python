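"""Rheogram inversion: closed-form pieces and the fixed-point procedure."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from oxyrheo.device import ChannelGeometry, network_resistance
from oxyrheo.pipeline import fit_rheograms
from oxyrheo.synthetic import (
    BloodModel,
    default_pressure_steps,
    forward_operating_point,
    generate_trace,
)
from oxyrheo.viscometry import (
    InversionSettings,
    RheologyTrace,
    ViscosityRatioFactors,
    average_shear_rate,
    experimental_flow_from_velocity,
    infer_rheogram,
    total_flow,
    viscosity_eq7,
)


def newtonian_model(eta: float) -> BloodModel:
    return BloodModel(
        po2_anchors=(0.0,), n_anchors=(1.0,), k_anchors_pa_sn=(eta,), noise_cv=0.0
    )


def power_law_model(n: float, k: float) -> BloodModel:
    return BloodModel(po2_anchors=(0.0,), n_anchors=(n,), k_anchors_pa_sn=(k,), noise_cv=0.0)


class TestAverageShearRate:
    @pytest.mark.parametrize(
        "umax, half_width, expected",
        [(750.0, 7.5, 100.0), (0.0, 7.5, 0.0), (3500.0, 7.5, 466.67)],
    )
    def test_values(self, umax, half_width, expected):
        assert average_shear_rate(umax, half_width) == pytest.approx(expected, rel=1e-4)

    def test_invalid_half_width(self):
        with pytest.raises(ValueError):
            average_shear_rate(100.0, 0.0)


class TestFlowConversions:
    def test_experimental_flow_value(self):
        geo = ChannelGeometry(15e-6, 15e-6, 8e-3, "square")
        q = experimental_flow_from_velocity(3.5e-3, geo, 0.477)
        assert q == pytest.approx(3.756e-13, rel=1e-3)

    def test_plug_flow_factor(self):
        geo = ChannelGeometry(15e-6, 15e-6, 8e-3, "square")
        q = experimental_flow_from_velocity(1e-3, geo, 1.0)
        assert q == pytest.approx(1e-3 * 15e-6 * 15e-6, rel=1e-12)

    def test_profile_factor_matches_duct_series_solution(self):
        """0.477 equals the laminar square-duct mean/max ratio to 3 decimals.

        Independent oracle: the Fourier-series velocity profile of pressure-
        driven flow in a square duct, integrated by quadrature.
        """
        m = 401
        y = np.linspace(0.0, 1.0, m)
        z = np.linspace(0.0, 1.0, m)
        yy, zz = np.meshgrid(y, z, indexing="ij")
        u = np.zeros_like(yy)
        for k in range(1, 200, 2):
            u += (
                (1.0 / k**3)
                * (1 - np.cosh(k * np.pi * (yy - 0.5)) / np.cosh(k * np.pi * 0.5))
                * np.sin(k * np.pi * zz)
            )
        ratio = np.trapezoid(np.trapezoid(u, z, axis=1), y) / u.max()
        assert ratio == pytest.approx(0.477, abs=5e-4)

    def test_total_flow_symmetric_branches(self, spec_constants_network):
        net = dataclasses.replace(
            spec_constants_network,
            bypass=dataclasses.replace(spec_constants_network.bypass, c_per_m3=1e16),
        )
        q = total_flow(1e-13, net, ViscosityRatioFactors())
        assert q == pytest.approx(2e-13, rel=1e-12)

    def test_total_flow_viscous_bypass_limit(self, spec_constants_network):
        q = total_flow(1e-13, spec_constants_network, ViscosityRatioFactors(a=1.0, b=1e12))
        assert q == pytest.approx(1e-13, rel=1e-9)

    def test_total_flow_value(self, spec_constants_network):
        q = total_flow(1e-13, spec_constants_network, ViscosityRatioFactors())
        assert q == pytest.approx(3.5e-13, rel=1e-12)


class TestViscosityInversion:
    def test_newtonian_round_trip_spec_constants(self, spec_constants_network):
        """Forward circuit at eta=4 cP, inverted with A=B=1, returns 4 cP."""
        dp_over_q = network_resistance(spec_constants_network, 0.004, 0.004, 0.004)
        eta3 = viscosity_eq7(dp_over_q * 1e-13, 1e-13, spec_constants_network, ViscosityRatioFactors())
        assert eta3 == pytest.approx(0.004, rel=1e-12)

    @hsettings(max_examples=100, deadline=None, derandomize=True)
    @given(
        eta=st.floats(1e-4, 0.1),
        c1=st.floats(1e14, 1e19),
        c2=st.floats(1e14, 1e19),
        c3=st.floats(1e14, 1e19),
        q=st.floats(1e-15, 1e-10),
    )
    def test_newtonian_identity_any_constants(self, eta, c1, c2, c3, q):
        """Forward then inverse is the identity for a Newtonian fluid."""
        from oxyrheo.device import DeviceNetwork, HydraulicResistor

        net = DeviceNetwork(
            inlet_resistor=HydraulicResistor.from_constant("inlet_resistor", c1),
            bypass=HydraulicResistor.from_constant("bypass", c2),
            experimental=HydraulicResistor.from_constant("experimental", c3),
        )
        dp = q * network_resistance(net, eta, eta, eta)
        assert viscosity_eq7(dp, q, net, ViscosityRatioFactors()) == pytest.approx(
            eta, rel=1e-12
        )

    def test_linearity_in_pressure(self, spec_constants_network):
        f = ViscosityRatioFactors()
        e1 = viscosity_eq7(1000.0, 1e-13, spec_constants_network, f)
        e2 = viscosity_eq7(2000.0, 1e-13, spec_constants_network, f)
        assert e2 == pytest.approx(2 * e1, rel=1e-12)

    def test_invalid_inputs(self, spec_constants_network):
        with pytest.raises(ValueError):
            viscosity_eq7(0.0, 1e-13, spec_constants_network, ViscosityRatioFactors())
        with pytest.raises(ValueError):
            ViscosityRatioFactors(a=0.0)


class TestInferRheogram:
    def test_newtonian_trace_flat_rheogram(self, network, pressure_steps):
        eta0 = 0.005
        trace, _ = generate_trace(
            newtonian_model(eta0), network, pressure_steps,
            oxygen_schedule_mmhg=[92.0], seed=0, include_transient=False,
        )
        rheo = infer_rheogram(trace, network)[92.0]
        assert rheo.converged
        np.testing.assert_allclose(rheo.viscosities, eta0, rtol=1e-8)

    @pytest.mark.parametrize("n_true", [0.6, 0.8, 1.0])
    def test_power_law_round_trip_against_forward_oracle(self, network, n_true):
        """Noiseless power-law blood: the fixed point recovers the generating
        viscosity curve within 1% at every step, and the fitted index within 0.01.

        The forward data come from a brute-force nonlinear solve of the circuit
        (bracketed root finding, no fixed point), so this is a genuine
        inverse-vs-independent-oracle comparison.
        """
        k_true = 0.015
        model = power_law_model(n_true, k_true)
        trace, truth = generate_trace(
            model, network, default_pressure_steps(),
            oxygen_schedule_mmhg=[92.0], seed=0, include_transient=False,
        )
        rheo = infer_rheogram(trace, network)[92.0]
        expected = k_true * rheo.shear_rates ** (n_true - 1.0)
        np.testing.assert_allclose(rheo.viscosities, expected, rtol=0.01)
        fit = fit_rheograms({92.0: rheo})[0]
        assert abs(fit.n - n_true) < 0.01

    @pytest.mark.parametrize("n_true", [0.7, 0.9])
    def test_converged_solution_satisfies_circuit_equation(self, network, n_true):
        """Residual |dp - Q*R_hyd(eta1,eta2,eta3)|/dp < 1e-6 at every step,
        with section viscosities recomputed independently from the material law."""
        model = power_law_model(n_true, 0.02)
        steps = default_pressure_steps()
        trace, _ = generate_trace(
            model, network, steps, oxygen_schedule_mmhg=[92.0], seed=0,
            include_transient=False,
        )
        rheo = infer_rheogram(trace, network)[92.0]
        for dp in steps:
            op = forward_operating_point(model, network, float(dp), 92.0)
            r_hyd = network_resistance(
                network, op["eta1_pa_s"], op["eta2_pa_s"], op["eta3_pa_s"]
            )
            assert abs(dp - op["q_total_m3_s"] * r_hyd) / dp < 1e-6

    def test_monotone_pressure_monotone_flow(self, network):
        for n_true in (0.6, 0.8, 1.0):
            model = power_law_model(n_true, 0.02)
            q = [
                forward_operating_point(model, network, p, 92.0)["q_total_m3_s"]
                for p in default_pressure_steps()
            ]
            assert np.all(np.diff(q) > 0)

    def test_all_zero_velocities_rejected(self, network):
        df = pd.DataFrame(
            {
                "time_s": [0.0, 1.0, 2.0, 3.0, 4.0, 5.0],
                "pressure_pa": [1e3, 1e3, 2e3, 2e3, 4e3, 4e3],
                "po2_mmhg": [92.0] * 6,
                "umax_um_s": [0.0] * 6,
                "replicate": [0, 1, 0, 1, 0, 1],
            }
        )
        trace = RheologyTrace(records=df)
        with pytest.raises(ValueError, match="zero"):
            infer_rheogram(trace, network)

    def test_too_few_steps_rejected(self, network, noiseless_sickle_model):
        trace, _ = generate_trace(
            noiseless_sickle_model, network, [1e3, 5e3],
            oxygen_schedule_mmhg=[92.0], seed=0,
        )
        with pytest.raises(ValueError, match="at least 3"):
            infer_rheogram(trace, network)

    def test_steady_state_windowing_rejects_transients(self, network):
        """With transient captures present, the default window recovers the
        exact index; disabling the window biases the inversion."""
        model = power_law_model(0.8, 0.015)
        trace, _ = generate_trace(
            model, network, default_pressure_steps(),
            oxygen_schedule_mmhg=[92.0], seed=0, include_transient=True,
        )
        n_windowed = fit_rheograms(infer_rheogram(trace, network))[0].n
        no_window = InversionSettings(steady_state_fraction=1.0)
        n_raw = fit_rheograms(infer_rheogram(trace, network, no_window))[0].n
        assert abs(n_windowed - 0.8) < 1e-6
        assert abs(n_raw - 0.8) > abs(n_windowed - 0.8)

    def test_area_proportional_rule_close_but_distinct(self, network):
        """The literal area-proportional linearization converges and lands near
        the continuity result; the two differ measurably in K."""
        model = power_law_model(0.8, 0.015)
        trace, _ = generate_trace(
            model, network, default_pressure_steps(),
            oxygen_schedule_mmhg=[92.0], seed=0, include_transient=False,
        )
        fit_cont = fit_rheograms(infer_rheogram(trace, network))[0]
        area = InversionSettings(velocity_rule="area_proportional")
        fit_area = fit_rheograms(infer_rheogram(trace, network, area))[0]
        assert abs(fit_area.n - fit_cont.n) < 0.05
        assert fit_area.k_pa_sn != pytest.approx(fit_cont.k_pa_sn, rel=1e-6)

    def test_replicate_sd_propagates(self, network, sickle_model):
        trace, _ = generate_trace(
            sickle_model, network, default_pressure_steps(),
            oxygen_schedule_mmhg=[92.0], seed=3,
        )
        rheo = infer_rheogram(trace, network)[92.0]
        sds = np.array([p.sd_pa_s for p in rheo.points])
        assert np.all(sds > 0)
        # measurement SD ~ CV * eta, well below the viscosity itself
        assert np.all(sds < 0.3 * rheo.viscosities)
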