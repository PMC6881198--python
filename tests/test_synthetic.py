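"""Synthetic blood model, transfusion mixing, trace and cohort generation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hsettings, strategies as st
from scipy.optimize import bisect

from oxyrheo.synthetic import (
    BloodModel,
    BloodModelParams,
    CohortSpec,
    SampleComposition,
    build_blood_model,
    default_network,
    default_pressure_steps,
    generate_cohort,
    generate_trace,
    mix_transfusion,
    mixture_blood_model,
    transfusion_volume_fraction,
)


def sickle_comp(hbs=1.0, mchc=33.0):
    return SampleComposition(hct=0.25, mchc_g_dl=mchc, hbs=hbs, hba=1.0 - hbs)


class TestBloodModel:
    def test_anchor_values(self):
        m = build_blood_model(sickle_comp())
        assert m.n_at(92.0) == pytest.approx(0.76)
        assert m.n_at(46.0) == pytest.approx(0.74)
        assert m.n_at(0.0) == pytest.approx(0.87)

    def test_interpolation_midpoint(self):
        m = build_blood_model(sickle_comp())
        assert m.n_at(23.0) == pytest.approx(0.805)

    def test_constant_above_ambient_anchor(self):
        m = build_blood_model(sickle_comp())
        assert m.n_at(160.0) == pytest.approx(m.n_at(92.0))

    def test_healthy_blood_oxygen_independent(self):
        m = build_blood_model(SampleComposition(hct=0.25, hba=1.0))
        assert m.is_oxygen_independent()
        for po2 in (0.0, 46.0, 92.0, 160.0):
            assert m.n_at(po2) == pytest.approx(m.n_at(92.0))
            assert m.k_at(po2) == pytest.approx(m.k_at(92.0))

    def test_viscosity_increases_with_deoxygenation(self):
        """At the 100/s comparison shear rate, viscosity is strictly ordered
        0 mm Hg > 46 mm Hg > 92 mm Hg."""
        m = build_blood_model(sickle_comp())
        v = [m.viscosity(po2, 100.0) for po2 in (92.0, 46.0, 0.0)]
        assert v[0] < v[1] < v[2]

    def test_invalid_anchor_rejected(self):
        with pytest.raises(ValueError):
            BloodModel(po2_anchors=(0.0,), n_anchors=(-0.5,), k_anchors_pa_sn=(0.01,))
        with pytest.raises(ValueError):
            BloodModel(po2_anchors=(0.0,), n_anchors=(0.8,), k_anchors_pa_sn=(float("nan"),))


class TestMixTransfusion:
    def test_equal_mchc_volume_equals_mass(self):
        mixed = mix_transfusion(sickle_comp(1.0), sickle_comp(0.0), 0.30)
        assert mixed.hbs == pytest.approx(0.30, rel=1e-12)

    def test_v_zero_returns_donor(self):
        donor = SampleComposition(hct=0.25, mchc_g_dl=34.0, hba=0.97, hbf=0.03)
        mixed = mix_transfusion(sickle_comp(), donor, 0.0)
        assert mixed == donor

    def test_target_fraction_matches_bisection_oracle(self):
        """v for a 25% HbS target at unequal MCHCs, against an independent
        bisection solve of the mass balance."""
        sickle = SampleComposition(hct=0.25, mchc_g_dl=32.0, hbs=0.95, hba=0.05)
        donor = SampleComposition(hct=0.25, mchc_g_dl=34.0, hba=1.0)
        v = transfusion_volume_fraction(sickle, donor, 0.25)
        assert v == pytest.approx(0.2751, abs=2e-4)
        v_oracle = bisect(
            lambda vv: mix_transfusion(sickle, donor, vv).hbs - 0.25, 0.0, 1.0, xtol=1e-12
        )
        assert v == pytest.approx(v_oracle, abs=1e-10)

    @hsettings(max_examples=100, deadline=None, derandomize=True)
    @given(
        v=st.floats(0.0, 1.0),
        mchc_s=st.floats(28.0, 38.0),
        mchc_d=st.floats(28.0, 38.0),
        hbs_s=st.floats(0.5, 1.0),
    )
    def test_hemoglobin_mass_balance(self, v, mchc_s, mchc_d, hbs_s):
        """Total and per-species hemoglobin mass per unit volume is conserved."""
        sickle = SampleComposition(hct=0.25, mchc_g_dl=mchc_s, hbs=hbs_s, hba=1.0 - hbs_s)
        donor = SampleComposition(hct=0.25, mchc_g_dl=mchc_d, hba=0.97, hbf=0.03)
        mixed = mix_transfusion(sickle, donor, v)
        expect_total = v * sickle.hb_mass_per_dl_blood + (1 - v) * donor.hb_mass_per_dl_blood
        assert mixed.hb_mass_per_dl_blood == pytest.approx(expect_total, rel=1e-12)
        for species in ("hbs", "hba", "hbf"):
            expect = (
                v * sickle.hb_mass_per_dl_blood * getattr(sickle, species)
                + (1 - v) * donor.hb_mass_per_dl_blood * getattr(donor, species)
            )
            got = mixed.hb_mass_per_dl_blood * getattr(mixed, species)
            assert got == pytest.approx(expect, rel=1e-12, abs=1e-15)

    def test_mismatched_hct_rejected(self):
        with pytest.raises(ValueError, match="HCT"):
            mix_transfusion(
                sickle_comp(), SampleComposition(hct=0.45, mchc_g_dl=34.0, hba=1.0), 0.5
            )


class TestMixtureModel:
    def test_endpoints(self, sickle_model, healthy_model):
        at_zero = mixture_blood_model(sickle_model, healthy_model, 0.0)
        assert at_zero.n_anchors == healthy_model.n_anchors
        at_one = mixture_blood_model(sickle_model, healthy_model, 1.0)
        assert at_one.n_anchors == sickle_model.n_anchors

    def test_sensitivity_weighting(self, sickle_model, healthy_model):
        """s=2 at half the untransfused HbS leaves only w = 0.25 of the gap."""
        mix = mixture_blood_model(sickle_model, healthy_model, 0.5, sensitivity=2.0)
        for po2 in (0.0, 46.0, 92.0):
            gap = sickle_model.n_at(po2) - healthy_model.n_at(po2)
            assert mix.n_at(po2) - healthy_model.n_at(po2) == pytest.approx(0.25 * gap, abs=1e-12)

    def test_higher_sensitivity_recovers_earlier(self, sickle_model, healthy_model):
        """At 50% HbS, a high-sensitivity patient's 0 mm Hg index sits closer to
        healthy than a low-sensitivity patient's."""
        early = mixture_blood_model(sickle_model, healthy_model, 0.5, sensitivity=3.0)
        late = mixture_blood_model(sickle_model, healthy_model, 0.5, sensitivity=0.5)
        h = healthy_model.n_at(0.0)
        assert abs(early.n_at(0.0) - h) < abs(late.n_at(0.0) - h)

    def test_negative_sensitivity_rejected(self, sickle_model, healthy_model):
        with pytest.raises(ValueError):
            mixture_blood_model(sickle_model, healthy_model, 0.5, sensitivity=-1.0)

    def test_build_blood_model_intermediate_hbs(self):
        params = BloodModelParams()
        m = build_blood_model(sickle_comp(0.3), params)
        sickle = params.sickle_model()
        healthy = params.healthy_model()
        assert healthy.n_at(0.0) < m.n_at(0.0) < sickle.n_at(0.0)


class TestGenerateTrace:
    def test_determinism(self, network, sickle_model, pressure_steps):
        t1, _ = generate_trace(sickle_model, network, pressure_steps, seed=42)
        t2, _ = generate_trace(sickle_model, network, pressure_steps, seed=42)
        pd.testing.assert_frame_equal(t1.records, t2.records)

    def test_different_seed_differs(self, network, sickle_model, pressure_steps):
        t1, _ = generate_trace(sickle_model, network, pressure_steps, seed=1)
        t2, _ = generate_trace(sickle_model, network, pressure_steps, seed=2)
        assert not t1.records["umax_um_s"].equals(t2.records["umax_um_s"])

    def test_newtonian_velocity_linear_in_pressure(self, network):
        m = BloodModel(po2_anchors=(0.0,), n_anchors=(1.0,), k_anchors_pa_sn=(0.004,), noise_cv=0.0)
        _, truth = generate_trace(
            m, network, [1e3, 2e3, 4e3], oxygen_schedule_mmhg=[92.0], seed=0,
            include_transient=False,
        )
        u = [s["umax_um_s"] for s in truth["per_tension"][92.0]["steps"]]
        assert u[1] / u[0] == pytest.approx(2.0, rel=1e-9)
        assert u[2] / u[0] == pytest.approx(4.0, rel=1e-9)

    def test_power_law_pressure_flow_exponent(self, network):
        """All sections share the material law, so every section viscosity
        scales as Q**(n-1) and log u vs log dp has slope exactly 1/n."""
        n_true = 0.8
        m = BloodModel(po2_anchors=(0.0,), n_anchors=(n_true,), k_anchors_pa_sn=(0.015,), noise_cv=0.0)
        steps = default_pressure_steps()
        _, truth = generate_trace(
            m, network, steps, oxygen_schedule_mmhg=[92.0], seed=0, include_transient=False
        )
        u = np.array([s["umax_um_s"] for s in truth["per_tension"][92.0]["steps"]])
        slope = np.polyfit(np.log(steps), np.log(u), 1)[0]
        assert slope == pytest.approx(1.0 / n_true, rel=1e-8)

    def test_replicate_structure(self, network, sickle_model):
        trace, _ = generate_trace(
            sickle_model, network, [2e3, 5e3, 1e4], oxygen_schedule_mmhg=[92.0],
            replicates=18, seed=0,
        )
        for _, grp in trace.records.groupby("pressure_pa"):
            t0, t1 = grp["time_s"].min(), grp["time_s"].max()
            steady = grp[grp["time_s"] >= t0 + 0.5 * (t1 - t0)]
            assert len(steady) == 18


class TestGenerateCohort:
    def test_zero_between_subject_sd_identical_truth(self, network, sickle_model):
        spec = CohortSpec(
            n_patients=3, seed=0,
            between_subject_sd={92.0: 0.0, 46.0: 0.0, 0.0: 0.0},
            pressure_steps_pa=tuple(default_pressure_steps(4)),
            oxygen_tensions_mmhg=(92.0,),
            replicates_per_step=3,
        )
        _, truth = generate_cohort(spec, base_model=sickle_model, network=network)
        anchors = [p["n_anchors"] for p in truth["patients"]]
        assert all(a == anchors[0] for a in anchors)

    def test_seed_reproducibility(self, network, sickle_model):
        spec = CohortSpec(
            n_patients=2, seed=5, pressure_steps_pa=tuple(default_pressure_steps(4)),
            oxygen_tensions_mmhg=(92.0,), replicates_per_step=3,
        )
        t1, truth1 = generate_cohort(spec, base_model=sickle_model, network=network)
        t2, truth2 = generate_cohort(spec, base_model=sickle_model, network=network)
        assert truth1 == truth2
        for a, b in zip(t1, t2):
            pd.testing.assert_frame_equal(a.records, b.records)

    def test_cohort_truth_mean_near_population_anchor(self, network, sickle_model):
        """Sampler self-consistency: the 9-patient ground-truth mean at each
        tension lies within 3 standard errors of the population anchor."""
        spec = CohortSpec(
            n_patients=9, seed=0, pressure_steps_pa=tuple(default_pressure_steps(4)),
            replicates_per_step=3,
        )
        _, truth = generate_cohort(spec, base_model=sickle_model, network=network)
        for po2, anchor, sd in [(92.0, 0.76, 0.075), (46.0, 0.74, 0.049), (0.0, 0.87, 0.056)]:
            draws = [p["n_anchors"][po2] for p in truth["patients"]]
            se = sd / np.sqrt(9)
            assert abs(np.mean(draws) - anchor) < 3 * se

    def test_truncation_bounds_respected(self, network, sickle_model):
        spec = CohortSpec(
            n_patients=12, seed=3,
            between_subject_sd={92.0: 0.4, 46.0: 0.4, 0.0: 0.4},
            pressure_steps_pa=tuple(default_pressure_steps(4)),
            oxygen_tensions_mmhg=(92.0,), replicates_per_step=2,
        )
        _, truth = generate_cohort(spec, base_model=sickle_model, network=network)
        for p in truth["patients"]:
            for v in p["n_anchors"].values():
                assert 0.3 < v < 1.3
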