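"""Pathophysiological overlays: renal impairment, Child-Pugh hepatic
impairment, and elderly age scaling.

Renal impairment is expressed through creatinine clearance: the individual's
GFR is scaled by CLcr_i / CLcr_ref, which makes the filtration relation
(CL_R = f_GFR * fu * GFR) and the clearance-ratio relation
(CL_R,i = CL_R,ref * CLcr_i / CLcr_ref) mutually consistent.

Hepatic impairment applies the Child-Pugh overlay table exactly as printed
(hepatic/renal blood flow, other-organ flow fraction, liver volume,
hematocrit, binding-protein ontogeny).  In addition, GFR is scaled with
renal *plasma* flow (constant filtration fraction) so that the printed
renal-flow decline carries through to renal drug clearance — the
hepatorenal component of cirrhosis.  The lumped hepatic plasma clearance is
held at its input value (an optional per-class multiplier is available for
sensitivity analysis).
"""
from __future__ import annotations

import warnings
from typing import Dict, Literal, Tuple

from pydantic import BaseModel, Field

from .compound import CompoundParameters, scale_fu_for_binding
from .physiology import PERFUSED_TISSUES, PhysiologyParameters

CLCR_REFERENCE_ML_PER_MIN = 120.0

RENAL_CATEGORIES: Dict[str, float] = {
    "normal": 120.0,
    "mild": 65.0,
    "moderate": 40.0,
    "severe": 15.0,
}


class RenalImpairmentSpec(BaseModel):
    clcr_ml_per_min: float = Field(gt=0)
    category: Literal["normal", "mild", "moderate", "severe"] | None = None

    @classmethod
    def from_category(cls, category: str) -> "RenalImpairmentSpec":
        if category not in RENAL_CATEGORIES:
            raise ValueError(
                f"unknown renal category {category!r}; valid: {list(RENAL_CATEGORIES)}"
            )
        return cls(clcr_ml_per_min=RENAL_CATEGORIES[category], category=category)


class HepaticImpairmentModifiers(BaseModel):
    """One column of the Child-Pugh physiology-overlay table."""

    cp_class: Literal["healthy", "CP-A", "CP-B", "CP-C"]
    hepatic_flow_l_per_min: float = Field(gt=0)
    renal_flow_l_per_min: float = Field(gt=0)
    other_organ_flow_fraction: float = Field(gt=0)
    liver_volume_l: float = Field(gt=0)
    hematocrit: float = Field(gt=0, lt=1)
    albumin_ontogeny: float = Field(gt=0)
    agp_ontogeny: float = Field(gt=0)


HEPATIC_IMPAIRMENT: Dict[str, HepaticImpairmentModifiers] = {
    cls_: HepaticImpairmentModifiers(
        cp_class=cls_,
        hepatic_flow_l_per_min=hf,
        renal_flow_l_per_min=rf,
        other_organ_flow_fraction=of,
        liver_volume_l=lv,
        hematocrit=hct,
        albumin_ontogeny=alb,
        agp_ontogeny=agp,
    )
    for cls_, (hf, rf, of, lv, hct, alb, agp) in {
        "healthy": (0.44, 1.35, 1.0, 2.44, 0.47, 1.0, 1.0),
        "CP-A": (0.45, 0.94, 1.75, 1.32, 0.39, 0.81, 0.6),
        "CP-B": (0.79, 0.69, 2.25, 1.05, 0.37, 0.68, 0.56),
        "CP-C": (0.15, 0.51, 2.75, 0.53, 0.35, 0.5, 0.3),
    }.items()
}

# Documented age-decline rates (fractional loss per year past the onset age).
ELDERLY_SCALING = {
    "gfr_decline_per_year": 0.0075,  # past age 40
    "hepatic_flow_decline_per_year": 0.003,  # past age 30
    "muscle_volume_decline_per_year": 0.006,  # past age 30
    "liver_volume_decline_per_year": 0.003,
    "kidney_volume_decline_per_year": 0.003,
}


def scale_renal_clearance(
    cl_r_ref_l_per_h: float, clcr_ref_ml_per_min: float, clcr_i_ml_per_min: float
) -> float:
    """CL_R,i = CL_R,ref * CLcr_i / CLcr_ref (linear in CLcr)."""
    if clcr_ref_ml_per_min <= 0:
        raise ValueError("reference creatinine clearance must be > 0")
    return cl_r_ref_l_per_h * clcr_i_ml_per_min / clcr_ref_ml_per_min


def apply_renal_impairment(
    phys: PhysiologyParameters,
    cmp: CompoundParameters,
    spec: RenalImpairmentSpec,
    clcr_ref_ml_per_min: float = CLCR_REFERENCE_ML_PER_MIN,
) -> Tuple[PhysiologyParameters, CompoundParameters]:
    """Scale GFR by CLcr_i / CLcr_ref; all non-renal parameters untouched."""
    factor = spec.clcr_ml_per_min / clcr_ref_ml_per_min
    return phys.updated(gfr_ml_per_min=phys.gfr_ml_per_min * factor), cmp


def apply_hepatic_impairment(
    phys: PhysiologyParameters,
    cmp: CompoundParameters,
    mods: HepaticImpairmentModifiers,
    cl_h_multiplier: float = 1.0,
) -> Tuple[PhysiologyParameters, CompoundParameters]:
    """Overlay one Child-Pugh column onto a healthy baseline.

    Hepatic arterial flow, renal flow, liver volume and hematocrit are set to
    the column values; every other tissue flow is multiplied by the
    other-organ fraction; GFR is scaled with renal plasma flow; the unbound
    fraction is rescaled through the albumin ontogeny factor; cardiac output
    is recomputed to restore flow balance.  Raises if the baseline already
    carries an impairment overlay (ontogeny factors != 1).
    """
    if phys.albumin_ontogeny != 1.0 or phys.agp_ontogeny != 1.0:
        raise ValueError(
            "hepatic impairment must be applied to a healthy baseline "
            "(ontogeny factors are already != 1)"
        )
    flows = dict(phys.organ_blood_flows_l_per_min)
    old_renal_plasma = flows["kidney"] * (1.0 - phys.hematocrit)
    for organ in PERFUSED_TISSUES:
        if organ not in ("liver", "kidney"):
            flows[organ] = flows[organ] * mods.other_organ_flow_fraction
    flows["liver"] = mods.hepatic_flow_l_per_min
    flows["kidney"] = mods.renal_flow_l_per_min
    co = sum(flows[t] for t in PERFUSED_TISSUES)
    flows["lung"] = flows["arterial_blood"] = flows["venous_blood"] = co

    new_renal_plasma = mods.renal_flow_l_per_min * (1.0 - mods.hematocrit)
    gfr = phys.gfr_ml_per_min * new_renal_plasma / old_renal_plasma

    vols = dict(phys.organ_volumes_l)
    vols["liver"] = mods.liver_volume_l

    phys_out = phys.updated(
        organ_blood_flows_l_per_min=flows,
        organ_volumes_l=vols,
        hematocrit=mods.hematocrit,
        gfr_ml_per_min=gfr,
        albumin_ontogeny=mods.albumin_ontogeny,
        agp_ontogeny=mods.agp_ontogeny,
    )
    cmp_out = cmp.model_copy(
        update={
            "fu_plasma": scale_fu_for_binding(cmp, mods.albumin_ontogeny),
            "cl_h_l_per_h": cmp.cl_h_l_per_h * cl_h_multiplier,
        }
    )
    return phys_out, cmp_out


def scale_to_elderly(phys: PhysiologyParameters, target_age: float) -> PhysiologyParameters:
    """Age the individual using documented monotone decline functions.

    GFR declines past age 40; hepatic arterial flow and lean organ volumes
    (muscle, liver, kidney) decline past age 30, with the lost lean volume
    moved into adipose so body weight is conserved and the adipose fraction
    is non-decreasing.  Identity at the adult baseline age.
    """
    if target_age < phys.age_years:
        warnings.warn(
            f"target_age {target_age} is below the baseline age {phys.age_years}; "
            "no rejuvenation is applied",
            stacklevel=2,
        )
        return phys
    s = ELDERLY_SCALING
    years30 = max(0.0, target_age - 30.0)
    years40 = max(0.0, target_age - 40.0)
    gfr_factor = max(0.1, 1.0 - s["gfr_decline_per_year"] * years40)
    flow_factor = max(0.1, 1.0 - s["hepatic_flow_decline_per_year"] * years30)

    vols = dict(phys.organ_volumes_l)
    lost = 0.0
    for organ, key in (
        ("muscle", "muscle_volume_decline_per_year"),
        ("liver", "liver_volume_decline_per_year"),
        ("kidney", "kidney_volume_decline_per_year"),
    ):
        factor = max(0.1, 1.0 - s[key] * years30)
        new = vols[organ] * factor
        lost += vols[organ] - new
        vols[organ] = new
    vols["adipose"] += lost

    flows = dict(phys.organ_blood_flows_l_per_min)
    flows["liver"] = flows["liver"] * flow_factor
    co = sum(flows[t] for t in PERFUSED_TISSUES)
    flows["lung"] = flows["arterial_blood"] = flows["venous_blood"] = co

    return phys.updated(
        age_years=target_age,
        gfr_ml_per_min=phys.gfr_ml_per_min * gfr_factor,
        organ_volumes_l=vols,
        organ_blood_flows_l_per_min=flows,
    )
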