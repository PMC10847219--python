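import pytest
from hypothesis import given
from hypothesis import strategies as st

from apixpbpk import special_populations as sp
from apixpbpk.compound import renal_plasma_clearance, scale_fu_for_binding
from apixpbpk.physiology import PERFUSED_TISSUES


class TestRenalScaling:
    def test_identity_at_reference_creatinine_clearance(self):
        assert sp.scale_renal_clearance(1.2053, 120, 120) == pytest.approx(1.2053)

    def test_moderate_impairment_is_one_third(self):
        assert sp.scale_renal_clearance(1.2053, 120, 40) == pytest.approx(1.2053 * 40 / 120)

    def test_anuric_limit_is_zero(self):
        assert sp.scale_renal_clearance(5.0, 120, 0) == 0.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            sp.scale_renal_clearance(1.0, 0, 40)

    @given(cl=st.floats(0.01, 10), a=st.floats(1, 150), b=st.floats(1, 150))
    def test_linearity_in_creatinine_clearance(self, cl, a, b):
        f = lambda x: sp.scale_renal_clearance(cl, 120, x)  # noqa: E731
        assert f(a) + f(b) == pytest.approx(f(a + b), rel=1e-12)
        assert f(2 * a) == pytest.approx(2 * f(a), rel=1e-12)


class TestRenalImpairmentOverlay:
    @pytest.mark.parametrize(
        "category, factor", [("normal", 1.0), ("mild", 65 / 120), ("severe", 15 / 120)]
    )
    def test_renal_clearance_scales_with_category(
        self, reference_adult, apix, category, factor
    ):
        cl_ref = renal_plasma_clearance(apix, reference_adult)
        phys2, cmp2 = sp.apply_renal_impairment(
            reference_adult, apix, sp.RenalImpairmentSpec.from_category(category)
        )
        assert renal_plasma_clearance(cmp2, phys2) == pytest.approx(cl_ref * factor)

    def test_non_renal_parameters_untouched(self, reference_adult, apix):
        phys2, cmp2 = sp.apply_renal_impairment(
            reference_adult, apix, sp.RenalImpairmentSpec.from_category("moderate")
        )
        assert phys2.organ_volumes_l == reference_adult.organ_volumes_l
        assert phys2.organ_blood_flows_l_per_min == reference_adult.organ_blood_flows_l_per_min
        assert phys2.hematocrit == reference_adult.hematocrit
        assert cmp2 == apix

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="mild"):
            sp.RenalImpairmentSpec.from_category("terrible")


class TestHepaticImpairmentOverlay:
    @pytest.mark.parametrize("cls", ["CP-A", "CP-B", "CP-C"])
    def test_overlay_table_cells_reproduced_exactly(self, reference_adult, apix, cls):
        mods = sp.HEPATIC_IMPAIRMENT[cls]
        phys2, cmp2 = sp.apply_hepatic_impairment(reference_adult, apix, mods)
        assert phys2.organ_blood_flows_l_per_min["liver"] == mods.hepatic_flow_l_per_min
        assert phys2.organ_blood_flows_l_per_min["kidney"] == mods.renal_flow_l_per_min
        assert phys2.organ_volumes_l["liver"] == mods.liver_volume_l
        assert phys2.hematocrit == mods.hematocrit
        assert phys2.albumin_ontogeny == mods.albumin_ontogeny
        assert phys2.agp_ontogeny == mods.agp_ontogeny

    def test_printed_overlay_values(self):
        a, c = sp.HEPATIC_IMPAIRMENT["CP-A"], sp.HEPATIC_IMPAIRMENT["CP-C"]
        assert (a.liver_volume_l, a.hepatic_flow_l_per_min, a.hematocrit) == (1.32, 0.45, 0.39)
        assert (c.renal_flow_l_per_min, c.other_organ_flow_fraction, c.albumin_ontogeny) == (
            0.51, 2.75, 0.5,
        )

    def test_other_organ_flows_multiplied_and_balance_restored(self, reference_adult, apix):
        mods = sp.HEPATIC_IMPAIRMENT["CP-B"]
        phys2, _ = sp.apply_hepatic_impairment(reference_adult, apix, mods)
        for organ in PERFUSED_TISSUES:
            if organ in ("liver", "kidney"):
                continue
            assert phys2.organ_blood_flows_l_per_min[organ] == pytest.approx(
                reference_adult.organ_blood_flows_l_per_min[organ] * 2.25
            )
        co = phys2.cardiac_output_l_per_min
        assert sum(phys2.organ_blood_flows_l_per_min[t] for t in PERFUSED_TISSUES) == (
            pytest.approx(co, rel=1e-9)
        )

    def test_unbound_fraction_rescaled_by_albumin_ontogeny(self, reference_adult, apix):
        mods = sp.HEPATIC_IMPAIRMENT["CP-C"]
        _, cmp2 = sp.apply_hepatic_impairment(reference_adult, apix, mods)
        assert cmp2.fu_plasma == pytest.approx(scale_fu_for_binding(apix, 0.5))
        assert cmp2.cl_h_l_per_h == apix.cl_h_l_per_h  # lumped CL_H held

    def test_identity_modifiers_leave_physiology_unchanged(self, reference_adult, apix):
        phys2, cmp2 = sp.apply_hepatic_impairment(
            reference_adult, apix, sp.HEPATIC_IMPAIRMENT["healthy"]
        )
        assert phys2.organ_volumes_l == pytest.approx(reference_adult.organ_volumes_l)
        assert phys2.organ_blood_flows_l_per_min == pytest.approx(
            reference_adult.organ_blood_flows_l_per_min
        )
        assert phys2.hematocrit == reference_adult.hematocrit
        assert phys2.gfr_ml_per_min == pytest.approx(reference_adult.gfr_ml_per_min)
        assert cmp2.fu_plasma == apix.fu_plasma

    def test_double_application_rejected(self, reference_adult, apix):
        phys2, cmp2 = sp.apply_hepatic_impairment(
            reference_adult, apix, sp.HEPATIC_IMPAIRMENT["CP-A"]
        )
        with pytest.raises(ValueError, match="healthy baseline"):
            sp.apply_hepatic_impairment(phys2, cmp2, sp.HEPATIC_IMPAIRMENT["CP-B"])


class TestElderlyScaling:
    def test_identity_at_adult_baseline_age(self, reference_adult):
        aged = sp.scale_to_elderly(reference_adult, 30.0)
        assert aged.gfr_ml_per_min == reference_adult.gfr_ml_per_min
        assert aged.organ_volumes_l == pytest.approx(reference_adult.organ_volumes_l)
        assert aged.organ_blood_flows_l_per_min == pytest.approx(
            reference_adult.organ_blood_flows_l_per_min
        )

    def test_age_70_reduces_gfr_and_lean_mass(self, reference_adult):
        aged = sp.scale_to_elderly(reference_adult, 70.0)
        assert aged.gfr_ml_per_min < 120.0
        assert aged.organ_blood_flows_l_per_min["liver"] < 0.44
        assert aged.organ_volumes_l["muscle"] < reference_adult.organ_volumes_l["muscle"]

    def test_adipose_fraction_non_decreasing_and_weight_conserved(self, reference_adult):
        aged = sp.scale_to_elderly(reference_adult, 75.0)
        assert aged.organ_volumes_l["adipose"] > reference_adult.organ_volumes_l["adipose"]
        assert sum(aged.organ_volumes_l.values()) == pytest.approx(
            sum(reference_adult.organ_volumes_l.values())
        )

    @pytest.mark.parametrize("a, b", [(60, 70), (70, 81)])
    def test_monotone_decline_with_age(self, reference_adult, a, b):
        younger = sp.scale_to_elderly(reference_adult, a)
        older = sp.scale_to_elderly(reference_adult, b)
        assert older.gfr_ml_per_min <= younger.gfr_ml_per_min
        assert (
            older.organ_blood_flows_l_per_min["liver"]
            <= younger.organ_blood_flows_l_per_min["liver"]
        )

    def test_rejuvenation_warns_and_returns_input(self, reference_adult):
        with pytest.warns(UserWarning, match="below the baseline age"):
            out = sp.scale_to_elderly(reference_adult, 20.0)
        assert out is reference_adult

    def test_renal_and_elderly_scaling_commute(self, reference_adult, apix):
        spec = sp.RenalImpairmentSpec.from_category("moderate")
        a, _ = sp.apply_renal_impairment(
            sp.scale_to_elderly(reference_adult, 70.0), apix, spec
        )
        b_phys, _ = sp.apply_renal_impairment(reference_adult, apix, spec)
        b = sp.scale_to_elderly(b_phys, 70.0)
        assert a.gfr_ml_per_min == pytest.approx(b.gfr_ml_per_min, rel=1e-12)
        assert a.organ_volumes_l == pytest.approx(b.organ_volumes_l)
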