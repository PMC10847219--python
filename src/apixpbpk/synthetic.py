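"""Synthetic "observed" clinical datasets for end-to-end testing.

Every pipeline stage is exercised without external downloads by emulating
the sparse mean concentration-time profiles of the clinical studies the
model is judged against: single oral doses in healthy adults (5-50 mg),
twice-daily multiple doses (2.5-25 mg for 7 days), renal impairment groups
by creatinine clearance (120/65/40/15 mL/min), Child-Pugh hepatic
impairment (CP-A/B/C) and an elderly cohort (60-81 years, 50% women).

Each virtual subject receives log-normally perturbed physiology (organ
volumes/flows/GFR) and clearance/permeability, the group's impairment
overlay, and proportional log-normal residual noise at the sparse sampling
times (median-unbiased in log space, so fold-error statistics against the
generating model center on 1).  Group means are returned in the same CSV
dialect the reporting stage consumes.  All randomness is seeded.
"""
from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.optimize import least_squares

from . import special_populations as sp
from .compound import CompoundParameters, apixaban, compute_partition_coefficients
from .engine import (
    AbsorptionSettings,
    ConcentrationTimeProfile,
    DosingRegimen,
    simulate_individual,
)
from .physiology import (
    PhysiologyParameters,
    PopulationSpec,
    build_reference_individual,
    sample_population,
)

SINGLE_DOSE_TIMES_H = (0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0, 48.0, 72.0)
MULTI_DOSE_TIMES_H = (1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 144.0, 146.0, 148.0, 152.0, 156.0, 168.0)

#: Study designs: doses/levels, regimen template, subject counts (from the
#: source figure legends where printed; elderly count chosen).
GROUP_DESIGNS: Dict[str, dict] = {
    "healthy_single": {
        "arms": [("dose_5mg", 5.0), ("dose_10mg", 10.0), ("dose_25mg", 25.0), ("dose_50mg", 50.0)],
        "n_subjects": [6, 6, 6, 6],
        "regimen": {"n_doses": 1, "interval_h": 24.0, "duration_h": 72.0},
        "times": SINGLE_DOSE_TIMES_H,
    },
    "healthy_multi": {
        "arms": [("dose_2.5mg_bid", 2.5), ("dose_5mg_bid", 5.0), ("dose_10mg_bid", 10.0), ("dose_25mg_bid", 25.0)],
        "n_subjects": [6, 6, 6, 6],
        "regimen": {"n_doses": 14, "interval_h": 12.0, "duration_h": 168.0},
        "times": MULTI_DOSE_TIMES_H,
    },
    "renal": {
        "arms": [("clcr_120", 120.0), ("clcr_65", 65.0), ("clcr_40", 40.0), ("clcr_15", 15.0)],
        "n_subjects": [8, 10, 7, 7],
        "dose_mg": 10.0,
        "regimen": {"n_doses": 1, "interval_h": 24.0, "duration_h": 72.0},
        "times": SINGLE_DOSE_TIMES_H,
    },
    "hepatic": {
        "arms": [("healthy", "healthy"), ("CP-A", "CP-A"), ("CP-B", "CP-B"), ("CP-C", "CP-C")],
        "n_subjects": [16, 8, 8, 8],
        "dose_mg": 5.0,
        "regimen": {"n_doses": 1, "interval_h": 24.0, "duration_h": 72.0},
        "times": SINGLE_DOSE_TIMES_H,
    },
    "elderly": {
        "arms": [("elderly_60_81", None)],
        "n_subjects": [12],
        "dose_mg": 10.0,
        "age_range": (60.0, 81.0),
        "proportion_female": 0.5,
        "regimen": {"n_doses": 1, "interval_h": 24.0, "duration_h": 72.0},
        "times": SINGLE_DOSE_TIMES_H,
    },
}

CLEARANCE_PERTURBATION_CV_DEFAULT = 0.30


class SyntheticStudySpec(BaseModel):
    """Specification of one synthetic study group."""

    group: str
    n_subjects: Optional[int] = None
    sampling_times_h: Optional[Sequence[float]] = None
    noise_cv: float = Field(default=0.10, ge=0)
    parameter_perturbation_cv: float = Field(default=0.16, ge=0)
    clearance_perturbation_cv: Optional[float] = None
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SyntheticStudySpec":
        if self.group not in GROUP_DESIGNS:
            raise ValueError(f"unknown group {self.group!r}; valid: {list(GROUP_DESIGNS)}")
        duration = GROUP_DESIGNS[self.group]["regimen"]["duration_h"]
        times = self.sampling_times_h
        if times is not None:
            times = [float(t) for t in times]
            if any(t <= 0 or t > duration for t in times):
                raise ValueError(f"sampling times must lie in (0, {duration}] h")
            if sorted(times) != times:
                raise ValueError("sampling times must be increasing")
        return self

    @property
    def effective_clearance_cv(self) -> float:
        if self.clearance_perturbation_cv is not None:
            return self.clearance_perturbation_cv
        return 0.0 if self.parameter_perturbation_cv == 0 else CLEARANCE_PERTURBATION_CV_DEFAULT


def _lognormal(rng: np.random.Generator, cv: float) -> float:
    if cv == 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(rng.lognormal(-0.5 * sigma * sigma, sigma))


def _noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Median-unbiased proportional log-normal residual multipliers."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(sigma * rng.standard_normal(size))


def _subject_compound(cmp: CompoundParameters, rng: np.random.Generator, cv: float) -> CompoundParameters:
    return cmp.model_copy(
        update={
            "cl_h_l_per_h": cmp.cl_h_l_per_h * _lognormal(rng, cv),
            "peff_cm_per_min": cmp.peff_cm_per_min * _lognormal(rng, cv),
        }
    )


def _sample_at(profile: ConcentrationTimeProfile, times: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(profile.times_h, times)
    return profile.conc_ng_per_ml[idx]


def generate_observed_profiles(
    spec: SyntheticStudySpec,
    cmp: Optional[CompoundParameters] = None,
    base: Optional[PhysiologyParameters] = None,
    absorption: Optional[AbsorptionSettings] = None,
) -> pd.DataFrame:
    """Simulate every arm of a study group and return group mean +/- SD.

    Columns: group, arm, dose_mg, n_subjects, time_h, conc_ng_per_mL,
    conc_sd_ng_per_mL.
    """
    design = GROUP_DESIGNS[spec.group]
    cmp = cmp or apixaban()
    base = base or build_reference_individual(30.0, "male", 82.0, 180.0)
    times = np.asarray(spec.sampling_times_h or design["times"], dtype=float)
    rng = np.random.default_rng(spec.seed)
    rows: List[dict] = []
    for (arm_label, arm_value), n_default in zip(design["arms"], design["n_subjects"]):
        n = spec.n_subjects or n_default
        dose = design.get("dose_mg", arm_value if spec.group.startswith("healthy") else None)
        regimen = DosingRegimen(dose_mg=float(dose), **design["regimen"])
        pop_spec = PopulationSpec(
            n=n,
            age_range=design.get("age_range", (25.0, 35.0)),
            proportion_female=design.get("proportion_female", 0.0),
            variability_cv={
                "organ_volumes": spec.parameter_perturbation_cv,
                "organ_blood_flows": spec.parameter_perturbation_cv,
                "gfr": spec.parameter_perturbation_cv,
            },
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        subjects = sample_population(pop_spec, base)
        t_grid = np.unique(np.concatenate([[0.0], times]))
        conc = np.zeros((n, len(times)))
        for i, phys_i in enumerate(subjects):
            cmp_i = _subject_compound(cmp, rng, spec.effective_clearance_cv)
            phys_i2, cmp_i2 = phys_i, cmp_i
            if spec.group == "renal":
                phys_i2, cmp_i2 = sp.apply_renal_impairment(
                    phys_i, cmp_i, sp.RenalImpairmentSpec(clcr_ml_per_min=arm_value)
                )
            elif spec.group == "hepatic" and arm_value != "healthy":
                phys_i2, cmp_i2 = sp.apply_hepatic_impairment(
                    phys_i, cmp_i, sp.HEPATIC_IMPAIRMENT[arm_value]
                )
            elif spec.group == "elderly":
                phys_i2 = sp.scale_to_elderly(phys_i, phys_i.age_years)
            kp = compute_partition_coefficients(cmp_i2, phys_i2)
            prof = simulate_individual(
                phys_i2, cmp_i2, kp, regimen, t_grid, absorption, individual_id=f"{arm_label}_{i:02d}"
            )
            conc[i] = _sample_at(prof, times) * _noise(rng, spec.noise_cv, len(times))
        for j, t in enumerate(times):
            rows.append(
                {
                    "group": spec.group,
                    "arm": arm_label,
                    "dose_mg": regimen.dose_mg,
                    "n_subjects": n,
                    "time_h": float(t),
                    "conc_ng_per_mL": float(conc[:, j].mean()),
                    "conc_sd_ng_per_mL": float(conc[:, j].std(ddof=1)) if n > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)


def reference_predictions(
    spec: SyntheticStudySpec,
    cmp: Optional[CompoundParameters] = None,
    base: Optional[PhysiologyParameters] = None,
    absorption: Optional[AbsorptionSettings] = None,
) -> pd.DataFrame:
    """Engine predictions at the group's sampling times for the *base*
    individual of each arm (no sampling, no noise) — the 'model' side of a
    predicted-vs-observed comparison."""
    noiseless = spec.model_copy(
        update={"noise_cv": 0.0, "parameter_perturbation_cv": 0.0, "clearance_perturbation_cv": 0.0,
                "n_subjects": 1}
    )
    return generate_observed_profiles(noiseless, cmp, base, absorption)


def validation_closure_afe(
    seed: int,
    group: str = "healthy_single",
    noise_cv: float = 0.10,
    parameter_perturbation_cv: float = 0.16,
    cmp: Optional[CompoundParameters] = None,
) -> float:
    """Simulate -> observe -> AFE closure on one study group.

    Returns the average fold error of the base-model predictions against the
    synthetic observed group means (all arms pooled).
    """
    from .nca import average_fold_error

    spec = SyntheticStudySpec(
        group=group, noise_cv=noise_cv,
        parameter_perturbation_cv=parameter_perturbation_cv, seed=seed,
    )
    observed = generate_observed_profiles(spec, cmp)
    predicted = reference_predictions(spec, cmp)
    merged = observed.merge(
        predicted[["arm", "time_h", "conc_ng_per_mL"]],
        on=["arm", "time_h"], suffixes=("_obs", "_pred"),
    )
    return average_fold_error(merged["conc_ng_per_mL_pred"], merged["conc_ng_per_mL_obs"])


class RecoveryReport(BaseModel):
    true_area_multiplier: float
    recovered_area_multiplier: float
    area_multiplier_rel_error: float
    true_cl_h_l_per_h: float
    recovered_cl_h_l_per_h: float
    cl_h_rel_error: float
    n_subjects: int
    noise_cv: float
    seed: int


def parameter_recovery_study(
    seed: int,
    noise_cv: float = 0.10,
    n_subjects: int = 12,
    true_area_multiplier: float = 1.0,
    true_cl_h_l_per_h: float = 2.4,
    dose_mg: float = 2.5,
) -> RecoveryReport:
    """Generate synthetic data with known absorption area and CL_H, then
    re-fit both from the noisy group mean profile.

    All subjects share the known parameters (residual noise only), so the
    recovered values estimate exactly the quantities that were planted.
    """
    rng = np.random.default_rng(seed)
    base = build_reference_individual(30.0, "male", 82.0, 180.0)
    cmp_true = apixaban().model_copy(update={"cl_h_l_per_h": true_cl_h_l_per_h})
    truth_abs = AbsorptionSettings(area_multiplier=true_area_multiplier)
    regimen = DosingRegimen(dose_mg=dose_mg, n_doses=1, interval_h=24.0, duration_h=72.0)
    times = np.asarray(SINGLE_DOSE_TIMES_H)
    t_grid = np.unique(np.concatenate([[0.0], times]))
    kp_true = compute_partition_coefficients(cmp_true, base)
    clean = _sample_at(
        simulate_individual(base, cmp_true, kp_true, regimen, t_grid, truth_abs), times
    )
    observed = np.vstack(
        [clean * _noise(rng, noise_cv, len(times)) for _ in range(n_subjects)]
    ).mean(axis=0)

    log_obs = np.log(np.clip(observed, 1e-12, None))

    def residuals(x: np.ndarray) -> np.ndarray:
        mult, cl_h = 10.0 ** x[0], 10.0 ** x[1]
        cmp_i = cmp_true.model_copy(update={"cl_h_l_per_h": cl_h})
        kp_i = compute_partition_coefficients(cmp_i, base)
        settings = AbsorptionSettings(area_multiplier=mult)
        pred = _sample_at(
            simulate_individual(base, cmp_i, kp_i, regimen, t_grid, settings), times
        )
        return np.log(np.clip(pred, 1e-12, None)) - log_obs

    fit = least_squares(residuals, x0=np.array([0.0, math.log10(2.4)]), method="lm")
    rec_mult, rec_cl_h = 10.0 ** fit.x[0], 10.0 ** fit.x[1]
    return RecoveryReport(
        true_area_multiplier=true_area_multiplier,
        recovered_area_multiplier=rec_mult,
        area_multiplier_rel_error=abs(rec_mult - true_area_multiplier) / true_area_multiplier,
        true_cl_h_l_per_h=true_cl_h_l_per_h,
        recovered_cl_h_l_per_h=rec_cl_h,
        cl_h_rel_error=abs(rec_cl_h - true_cl_h_l_per_h) / true_cl_h_l_per_h,
        n_subjects=n_subjects,
        noise_cv=noise_cv,
        seed=seed,
    )
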