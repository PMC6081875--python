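"""Marrow dose equations: blood method, mass scaling, ROB assembly."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from marrowdose import (
    PatientContext,
    PhantomReference,
    SourceActivitySet,
    blood_dose,
    compute_dose_report,
    organ_dose,
    rmblr,
    rob_dose,
    rob_tia,
    scale_svalue,
    total_bm_dose,
)
from marrowdose.errors import (
    ConfigurationError,
    DomainError,
    InconsistencyError,
)


class TestRmblr:
    def test_psma_is_rmecff_over_plasmacrit(self):
        assert rmblr("psma617", hct=0.5, rmecff=0.19) == pytest.approx(0.38)

    @pytest.mark.parametrize("hct", [0.3, 0.41, 0.5])
    def test_octreotate_is_unity(self, hct):
        assert rmblr("octreotate", hct) == 1.0

    def test_hand_evaluation_at_clinical_haematocrit(self):
        # HCT 0.376 -> 0.19 / 0.624
        assert rmblr("psma617", 0.376) == pytest.approx(0.19 / 0.624, rel=1e-12)

    @pytest.mark.parametrize("hct", [0.0, 1.0, -0.1, 1.3])
    def test_haematocrit_domain(self, hct):
        with pytest.raises(DomainError):
            rmblr("psma617", hct)


class TestScaleSValue:
    def test_identity_scaling_when_patient_equals_phantom(self, toy_phantom, toy_patient):
        assert scale_svalue("bm_self", toy_phantom, toy_patient) == pytest.approx(
            toy_phantom.s_bm_bm, rel=1e-12
        )
        for organ in toy_phantom.s_bm_organ:
            assert scale_svalue(
                "organ_to_bm", toy_phantom, toy_patient, organ=organ
            ) == pytest.approx(toy_phantom.s_bm_organ[organ], rel=1e-12)
        assert scale_svalue("wb_to_bm", toy_phantom, toy_patient) == pytest.approx(
            toy_phantom.s_bm_wb, rel=1e-12
        )

    def test_power_law_on_marrow_mass(self, toy_phantom, toy_patient):
        toy_patient.m_bm_kg = 2.0 * toy_phantom.m_bm_kg
        assert scale_svalue("bm_self", toy_phantom, toy_patient) == pytest.approx(
            0.5 * toy_phantom.s_bm_bm, rel=1e-12
        )

    def test_rob_terms_match_hand_evaluation(self, toy_phantom, toy_patient):
        terms = scale_svalue("rob_terms", toy_phantom, toy_patient)
        m_rob = 70.0 - 1.0 - (0.3 + 1.8 + 0.18)
        assert terms["wb"] == pytest.approx(1e-11, rel=1e-12)
        assert terms["bm"] == pytest.approx(1e-10 * (1.0 / m_rob), rel=1e-12)
        assert terms["organs"]["kidneys"] == pytest.approx(2e-12 * 0.3 / m_rob, rel=1e-12)
        assert terms["organs"]["liver"] == pytest.approx(1e-12 * 1.8 / m_rob, rel=1e-12)
        assert terms["organs"]["spleen"] == pytest.approx(
            1.5e-12 * 0.18 / m_rob, rel=1e-12
        )

    def test_organ_required_for_organ_kind(self, toy_phantom, toy_patient):
        with pytest.raises(ConfigurationError):
            scale_svalue("organ_to_bm", toy_phantom, toy_patient)


def unit_phantom_and_patient(therapy="octreotate", hct=0.5):
    """All factors one in consistent units: 1 g marrow, unit S values."""
    phantom = PhantomReference(
        sex="male",
        m_wb_kg=1.0,
        m_bm_kg=0.001,
        m_organ_kg={},
        s_bm_bm=1.0,
        s_bm_wb=1.0,
        s_bm_organ={},
        a=1.0,
        b=1.0,
        c=1.0,
    )
    patient = PatientContext(
        patient_id="U",
        sex="male",
        therapy=therapy,
        injected_activity_bq=1e9,
        m_wb_kg=1.0,
        hct=hct,
        m_bm_kg=0.001,
    )
    return phantom, patient


class TestBloodDose:
    def test_unit_product(self):
        phantom, patient = unit_phantom_and_patient()
        assert blood_dose(1.0, patient, phantom) == pytest.approx(1.0, rel=1e-12)

    def test_rmblr_isolates_therapy_difference(self):
        # HCT 0.62 -> PSMA RMBLR = 0.19/0.38 = 0.5, octreotate = 1
        ph_o, pat_o = unit_phantom_and_patient("octreotate", hct=0.62)
        ph_p, pat_p = unit_phantom_and_patient("psma617", hct=0.62)
        d_o = blood_dose(123.0, pat_o, ph_o)
        d_p = blood_dose(123.0, pat_p, ph_p)
        assert d_p == pytest.approx(0.5 * d_o, rel=1e-12)

    def test_negative_tia_rejected(self):
        phantom, patient = unit_phantom_and_patient()
        with pytest.raises(DomainError):
            blood_dose(-1.0, patient, phantom)


class TestOrganDose:
    def test_identity_masses_give_tia_times_svalue(self, toy_phantom, toy_patient):
        d = organ_dose(1e10, "kidneys", toy_patient, toy_phantom)
        assert d == pytest.approx(1e10 * 2e-12, rel=1e-12)

    def test_doubling_patient_organ_mass_halves_dose(self, toy_phantom, toy_patient):
        d1 = organ_dose(1e10, "liver", toy_patient, toy_phantom)
        toy_patient.m_organ_kg["liver"] *= 2.0
        d2 = organ_dose(1e10, "liver", toy_patient, toy_phantom)
        assert d2 == pytest.approx(0.5 * d1, rel=1e-12)

    def test_three_organ_sum_matches_hand_evaluation(self, toy_phantom, toy_patient):
        tias = {"kidneys": 2e10, "liver": 4e10, "spleen": 1e10}
        total = sum(
            organ_dose(tia, organ, toy_patient, toy_phantom)
            for organ, tia in tias.items()
        )
        expected = 2e10 * 2e-12 + 4e10 * 1e-12 + 1e10 * 1.5e-12
        assert total == pytest.approx(expected, rel=1e-12)

    def test_unknown_organ_rejected(self, toy_phantom, toy_patient):
        with pytest.raises(ConfigurationError):
            organ_dose(1e9, "pancreas", toy_patient, toy_phantom)


class TestRobTia:
    def test_simple_subtraction(self, toy_phantom, toy_patient):
        # zero blood concentration: ROB = WB - organs
        result = rob_tia(100.0, 0.0, toy_patient, toy_phantom, {"kidneys": 30.0})
        assert result == pytest.approx(70.0)

    def test_negative_result_raises_in_strict_mode(self, toy_phantom, toy_patient):
        with pytest.raises(InconsistencyError):
            rob_tia(100.0, 0.0, toy_patient, toy_phantom, {"kidneys": 130.0})

    def test_clamp_mode_floors_at_zero(self, toy_phantom, toy_patient):
        assert (
            rob_tia(100.0, 0.0, toy_patient, toy_phantom, {"kidneys": 130.0}, mode="clamp")
            == 0.0
        )

    def test_blood_term_uses_marrow_mass_in_grams(self, toy_phantom, toy_patient):
        # octreotate RMBLR = 1; marrow mass 1 kg = 1000 g
        result = rob_tia(5000.0, 1.0, toy_patient, toy_phantom, {})
        assert result == pytest.approx(5000.0 - 1000.0)


class TestRobDose:
    def test_two_term_bracket_hand_evaluation(self, toy_phantom, toy_patient):
        # no organs in the bracket: hand-computed WB minus marrow term
        m_rob = toy_patient.rob_mass_kg(toy_phantom)
        expected_bracket = 1e-11 - 1e-10 * (1.0 / m_rob) * (1.0 / 1.0)
        d = rob_dose(1e12, toy_patient, toy_phantom, organs_in_model=[])
        assert d == pytest.approx(1e12 * expected_bracket, rel=1e-12)

    def test_zero_tia_gives_zero_dose(self, toy_phantom, toy_patient):
        assert rob_dose(0.0, toy_patient, toy_phantom) == 0.0

    def test_linearity_in_tia(self, toy_phantom, toy_patient):
        d1 = rob_dose(1e11, toy_patient, toy_phantom)
        d2 = rob_dose(2e11, toy_patient, toy_phantom)
        assert d2 == pytest.approx(2 * d1, rel=1e-12)


class TestTotalDose:
    def test_sum_and_contributions(self):
        rep = total_bm_dose("X", "RP", 3e-3, {"kidneys": 2e-3}, 5e-3, 1e9)
        assert rep.d_total_gy == pytest.approx(10e-3)
        pc = rep.contributions_percent()
        assert pc == pytest.approx({"blood": 30.0, "organs": 20.0, "rob": 50.0})
        assert sum(pc.values()) == pytest.approx(100.0)

    def test_published_patient_normalisation(self):
        """92.6 mGy at 7.654 GBq injected is 12.1 mGy/GBq."""
        rep = total_bm_dose(
            "P1", "RP", 0.0926 * 0.63, {"k": 0.0926 * 0.08}, 0.0926 * 0.29, 7.654e9
        )
        assert rep.d_total_mgy_per_gbq == pytest.approx(12.1, abs=0.05)
        pc = rep.contributions_percent()
        assert pc["rob"] == pytest.approx(29, abs=0.5)
        assert pc["blood"] == pytest.approx(63, abs=0.5)

    @given(
        blood=st.floats(1e-4, 1.0),
        organ=st.floats(0.0, 1.0),
        rob=st.floats(1e-4, 1.0),
    )
    def test_contributions_always_close(self, blood, organ, rob):
        rep = total_bm_dose("H", "RP", blood, {"o": organ}, rob, 1e9)
        assert sum(rep.contributions_percent().values()) == pytest.approx(100.0)


class TestEndToEndLinearity:
    @given(scale=st.floats(0.1, 10.0))
    def test_dose_linear_in_all_tias(self, scale, toy_phantom, toy_patient):
        base = SourceActivitySet(
            tia_wb_bqh=5e11,
            tia_blood_conc_bqh_per_ml=1e7,
            tia_organ_bqh={"kidneys": 1e10, "liver": 2e10, "spleen": 5e9},
        )
        scaled = SourceActivitySet(
            tia_wb_bqh=base.tia_wb_bqh * scale,
            tia_blood_conc_bqh_per_ml=base.tia_blood_conc_bqh_per_ml * scale,
            tia_organ_bqh={k: v * scale for k, v in base.tia_organ_bqh.items()},
        )
        r1 = compute_dose_report(toy_patient, toy_phantom, base)
        r2 = compute_dose_report(toy_patient, toy_phantom, scaled)
        assert r2.d_total_gy == pytest.approx(scale * r1.d_total_gy, rel=1e-9)
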