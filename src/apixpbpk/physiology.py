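"""Reference human anatomy/physiology and virtual-population sampling.

The whole-body model uses 18 compartments: 15 perfused tissues, a lumped
"rest" compartment that absorbs unassigned mass and blood flow so that body
totals close, and arterial/venous blood pools.  Baseline organ volumes and
blood flows follow a documented reference-human table (ICRP Publication 89
reference adult, lightly adjusted; see ``REFERENCE_TABLE_SOURCE``) with the
hepatic/renal entries pinned to the healthy column of the disease-overlay
table used elsewhere in the package (hepatic arterial flow 0.44 L/min, renal
flow 1.35 L/min, liver volume 2.44 L, hematocrit 0.47, GFR 120 mL/min).

Volumes scale linearly with body weight and blood flows with weight^0.75
relative to the 82 kg reference male, so the reference individual reproduces
the pinned values exactly.
"""
from __future__ import annotations

import math
from typing import Dict, List, Literal, Tuple

import numpy as np
from pydantic import BaseModel, Field, model_validator

# Compartment bookkeeping -------------------------------------------------

ORGANS: Tuple[str, ...] = (
    "lung", "heart", "brain", "muscle", "adipose", "skin", "bone",
    "liver", "kidney", "spleen", "pancreas", "stomach", "small_intestine",
    "large_intestine", "gonads", "rest", "arterial_blood", "venous_blood",
)

#: tissues receiving an arterial inflow of their own (everything except the
#: lung, which receives the full cardiac output, and the two blood pools)
PERFUSED_TISSUES: Tuple[str, ...] = tuple(
    o for o in ORGANS if o not in ("lung", "arterial_blood", "venous_blood")
)

#: splanchnic organs draining into the portal vein (their venous outflow
#: enters the liver, not the central venous pool)
PORTAL_ORGANS: Tuple[str, ...] = (
    "spleen", "pancreas", "stomach", "small_intestine", "large_intestine",
)

REFERENCE_TABLE_SOURCE = (
    "ICRP Publication 89 reference adult male (73 kg) rescaled to 82 kg; "
    "hepatic arterial flow, renal flow, liver volume, hematocrit and GFR "
    "pinned to the healthy column of the hepatic-impairment overlay table."
)

REFERENCE_BODY_WEIGHT_KG = 82.0

# Organ volumes (L) at the 82 kg / 180 cm reference male.  "rest" closes the
# total body volume (body density ~1.05 kg/L -> ~78.1 L).
_REFERENCE_VOLUMES_L: Dict[str, float] = {
    "lung": 0.55,
    "heart": 0.35,
    "brain": 1.45,
    "muscle": 30.0,
    "adipose": 17.5,
    "skin": 3.4,
    "bone": 10.2,
    "liver": 2.44,
    "kidney": 0.31,
    "spleen": 0.19,
    "pancreas": 0.15,
    "stomach": 0.16,
    "small_intestine": 0.67,
    "large_intestine": 0.38,
    "gonads": 0.04,
    "arterial_blood": 1.70,
    "venous_blood": 3.90,
    "rest": 4.71,
}

# Arterial inflows (L/min); liver entry is the hepatic *arterial* flow only
# (portal inflow is the sum over PORTAL_ORGANS).  Cardiac output = sum = 6.5.
_REFERENCE_FLOWS_L_PER_MIN: Dict[str, float] = {
    "heart": 0.26,
    "brain": 0.78,
    "muscle": 1.10,
    "adipose": 0.33,
    "skin": 0.33,
    "bone": 0.33,
    "liver": 0.44,
    "kidney": 1.35,
    "spleen": 0.20,
    "pancreas": 0.07,
    "stomach": 0.07,
    "small_intestine": 0.65,
    "large_intestine": 0.26,
    "gonads": 0.003,
    "rest": 0.327,
}

_FEMALE_VOLUME_FACTORS = {"muscle": 0.85, "adipose": 1.25, "bone": 0.85}
_FEMALE_FLOW_FACTORS = {"muscle": 0.85, "adipose": 1.25}

REFERENCE_HEMATOCRIT = 0.47
REFERENCE_GFR_ML_PER_MIN = 120.0

#: Named demographic presets.  The Chinese presets are implementer-documented
#: means (no anthropometrics are printed for these cohorts in the source
#: clinical tables); they differ from the European reference only in body
#: size, which propagates through the allometric organ scaling.
DEMOGRAPHIC_PRESETS: Dict[str, Dict[str, object]] = {
    "european_adult": {"age": 30.0, "sex": "male", "body_weight_kg": 82.0, "height_cm": 180.0},
    "chinese_adult": {"age": 30.0, "sex": "male", "body_weight_kg": 63.0, "height_cm": 168.0},
    "chinese_elderly": {"age": 70.0, "sex": "male", "body_weight_kg": 61.0, "height_cm": 165.0},
}

FLOW_BALANCE_RTOL = 1e-6


class PhysiologyParameters(BaseModel):
    """A single individual's anatomy and physiology.

    ``organ_blood_flows_l_per_min`` stores the arterial inflow of each
    perfused tissue (liver: hepatic arterial flow only); the ``lung``,
    ``arterial_blood`` and ``venous_blood`` entries all equal the cardiac
    output.
    """

    age_years: float = Field(gt=0)
    sex: Literal["male", "female"]
    body_weight_kg: float = Field(gt=0)
    height_cm: float = Field(gt=0)
    hematocrit: float = Field(gt=0, lt=1)
    gfr_ml_per_min: float = Field(ge=0)
    organ_volumes_l: Dict[str, float]
    organ_blood_flows_l_per_min: Dict[str, float]
    albumin_ontogeny: float = Field(default=1.0, gt=0, le=3)
    agp_ontogeny: float = Field(default=1.0, gt=0, le=3)

    @property
    def bmi(self) -> float:
        """Body mass index, kg/m^2 (weight / (height/100)^2, exact)."""
        return self.body_weight_kg / (self.height_cm / 100.0) ** 2

    @property
    def cardiac_output_l_per_min(self) -> float:
        return self.organ_blood_flows_l_per_min["lung"]

    @model_validator(mode="after")
    def _check_invariants(self) -> "PhysiologyParameters":
        for name, table in (
            ("organ_volumes_l", self.organ_volumes_l),
            ("organ_blood_flows_l_per_min", self.organ_blood_flows_l_per_min),
        ):
            missing = set(ORGANS) - set(table)
            if missing:
                raise ValueError(f"{name} missing organs: {sorted(missing)}")
            bad = {k: v for k, v in table.items() if not v > 0}
            if bad:
                raise ValueError(f"{name} must be strictly positive, got {bad}")
        co = self.organ_blood_flows_l_per_min["lung"]
        tissue_sum = sum(self.organ_blood_flows_l_per_min[t] for t in PERFUSED_TISSUES)
        for label, value in (
            ("sum of tissue inflows", tissue_sum),
            ("arterial_blood", self.organ_blood_flows_l_per_min["arterial_blood"]),
            ("venous_blood", self.organ_blood_flows_l_per_min["venous_blood"]),
        ):
            if abs(value - co) > FLOW_BALANCE_RTOL * co:
                raise ValueError(
                    f"flow balance violated: {label} = {value} vs cardiac output {co}"
                )
        return self

    def updated(self, **changes) -> "PhysiologyParameters":
        """Return a re-validated copy with ``changes`` applied."""
        data = self.model_dump()
        data.update(changes)
        return PhysiologyParameters(**data)


class PopulationSpec(BaseModel):
    """Virtual-population sampling specification.

    ``variability_cv`` keys: ``organ_volumes``, ``organ_blood_flows``,
    ``gfr`` (log-normal coefficients of variation, mean-preserving).
    """

    n: int = Field(ge=1)
    age_range: Tuple[float, float] = (25.0, 35.0)
    proportion_female: float = Field(default=0.0, ge=0, le=1)
    variability_cv: Dict[str, float] = Field(
        default_factory=lambda: {"organ_volumes": 0.16, "organ_blood_flows": 0.16, "gfr": 0.16}
    )
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "PopulationSpec":
        if self.age_range[1] < self.age_range[0]:
            raise ValueError("age_range must be (low, high)")
        bad = {k: v for k, v in self.variability_cv.items() if v < 0}
        if bad:
            raise ValueError(f"CVs must be >= 0, got {bad}")
        return self


def build_reference_individual(
    age: float, sex: Literal["male", "female"], body_weight_kg: float, height_cm: float
) -> PhysiologyParameters:
    """Construct a complete healthy individual from demographics.

    Volumes scale with weight (exponent 1) and flows with weight^0.75 from
    the 82 kg reference male; female lean/adipose composition is adjusted
    multiplicatively.  Raises ``ValueError`` naming the offending field for
    out-of-range demographics.
    """
    if not (18.0 <= age <= 100.0):
        raise ValueError(f"age must be within [18, 100] years, got {age}")
    if body_weight_kg <= 0:
        raise ValueError(f"body_weight_kg must be positive, got {body_weight_kg}")
    if height_cm <= 0:
        raise ValueError(f"height_cm must be positive, got {height_cm}")
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")

    w = body_weight_kg / REFERENCE_BODY_WEIGHT_KG
    vols = {k: v * w for k, v in _REFERENCE_VOLUMES_L.items()}
    flows = {k: v * w**0.75 for k, v in _REFERENCE_FLOWS_L_PER_MIN.items()}
    if sex == "female":
        for organ, f in _FEMALE_VOLUME_FACTORS.items():
            vols[organ] *= f
        for organ, f in _FEMALE_FLOW_FACTORS.items():
            flows[organ] *= f
    co = sum(flows[t] for t in PERFUSED_TISSUES)
    flows["lung"] = flows["arterial_blood"] = flows["venous_blood"] = co
    return PhysiologyParameters(
        age_years=age,
        sex=sex,
        body_weight_kg=body_weight_kg,
        height_cm=height_cm,
        hematocrit=REFERENCE_HEMATOCRIT,
        gfr_ml_per_min=REFERENCE_GFR_ML_PER_MIN * w**0.75,
        organ_volumes_l=vols,
        organ_blood_flows_l_per_min=flows,
    )


def build_preset_individual(preset: str) -> PhysiologyParameters:
    """Build an individual from a named demographic preset."""
    try:
        demo = DEMOGRAPHIC_PRESETS[preset]
    except KeyError:
        raise ValueError(
            f"unknown preset {preset!r}; supported: {sorted(DEMOGRAPHIC_PRESETS)}"
        ) from None
    return build_reference_individual(
        float(demo["age"]), demo["sex"], float(demo["body_weight_kg"]), float(demo["height_cm"])
    )


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Mean-preserving log-normal multiplier(s) with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size) if size else 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def sample_population(
    spec: PopulationSpec, base: PhysiologyParameters
) -> List[PhysiologyParameters]:
    """Draw a seeded virtual population around ``base``.

    Organ volumes, tissue blood flows and GFR receive independent
    mean-preserving log-normal multipliers; cardiac output is recomputed so
    every sampled individual satisfies the flow-balance invariant.  Ages are
    drawn uniformly from ``spec.age_range`` and sex by ``proportion_female``
    (demographics are annotations here; age-dependent physiology is applied
    by :func:`apixpbpk.special_populations.scale_to_elderly`).
    """
    rng = np.random.default_rng(spec.seed)
    cv_vol = spec.variability_cv.get("organ_volumes", 0.0)
    cv_flow = spec.variability_cv.get("organ_blood_flows", 0.0)
    cv_gfr = spec.variability_cv.get("gfr", 0.0)
    out: List[PhysiologyParameters] = []
    for i in range(spec.n):
        age = rng.uniform(*spec.age_range)
        sex = "female" if rng.random() < spec.proportion_female else "male"
        vols = dict(base.organ_volumes_l)
        flows = dict(base.organ_blood_flows_l_per_min)
        for organ in ORGANS:
            if organ not in ("arterial_blood", "venous_blood"):
                vols[organ] = vols[organ] * _lognormal_factor(rng, cv_vol)
        for organ in PERFUSED_TISSUES:
            flows[organ] = flows[organ] * _lognormal_factor(rng, cv_flow)
        co = sum(flows[t] for t in PERFUSED_TISSUES)
        flows["lung"] = flows["arterial_blood"] = flows["venous_blood"] = co
        gfr = base.gfr_ml_per_min * _lognormal_factor(rng, cv_gfr)
        out.append(
            base.updated(
                age_years=age,
                sex=sex,
                organ_volumes_l=vols,
                organ_blood_flows_l_per_min=flows,
                gfr_ml_per_min=gfr,
            )
        )
    return out
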