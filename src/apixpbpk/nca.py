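"""Non-compartmental analysis, fold-error model metrics, and dose
normalization.

AUC(0-t) uses the linear trapezoidal rule; the terminal rate constant is
estimated by log-linear regression on the last 3..10 post-peak points,
choosing the window with the best adjusted r-squared (the common "best fit"
convention of NCA software).  AUC(0-inf) = AUC(0-t) + C_last / lambda_z and
is flagged missing when lambda_z is not estimable (r-squared < 0.8 or a
non-negative slope).

Reported ratios are rounded to 2 decimals and dose fractions to integer
percent (half-up), matching the precision of the clinical report tables
this stage mirrors; all internal arithmetic is exact.
"""
from __future__ import annotations

import logging
import math
from typing import Optional, Sequence, Tuple

import numpy as np
from pydantic import BaseModel, Field

from .engine import ConcentrationTimeProfile

logger = logging.getLogger(__name__)

LAMBDA_Z_MIN_POINTS = 3
LAMBDA_Z_MAX_POINTS = 10
LAMBDA_Z_MIN_R2 = 0.8


class PKParameters(BaseModel):
    """NCA exposure metrics for one concentration-time profile."""

    cmax_ng_per_ml: float = Field(ge=0)
    tmax_h: float = Field(ge=0)
    auc_0_t_ng_h_per_ml: float = Field(ge=0)
    auc_0_inf_ng_h_per_ml: Optional[float] = None
    lambda_z_per_h: Optional[float] = None
    t_half_h: Optional[float] = None
    extrapolated_fraction: Optional[float] = None
    n_lambda_z_points: Optional[int] = None
    lambda_z_adj_r2: Optional[float] = None


class DoseRecommendation(BaseModel):
    """Exposure ratios vs a reference population and the dose fraction that
    matches the reference AUC."""

    population_label: str
    auc_ratio_vs_reference: float = Field(gt=0)
    cmax_ratio_vs_reference: Optional[float] = None
    dose_fraction_percent: int = Field(gt=0)


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def auc_trapezoid(times_h: np.ndarray, conc: np.ndarray) -> float:
    return float(np.trapezoid(conc, times_h))


def _fit_lambda_z(times: np.ndarray, conc: np.ndarray):
    """Best adjusted-r2 log-linear fit over the last 3..10 post-peak points."""
    i_max = int(np.argmax(conc))
    t_term = times[i_max + 1:]
    c_term = conc[i_max + 1:]
    pos = c_term > 0
    t_term, c_term = t_term[pos], c_term[pos]
    best = None
    for k in range(LAMBDA_Z_MIN_POINTS, LAMBDA_Z_MAX_POINTS + 1):
        if k > len(t_term):
            break
        t_w = t_term[-k:]
        logc = np.log(c_term[-k:])
        slope, intercept = np.polyfit(t_w, logc, 1)
        resid = logc - (slope * t_w + intercept)
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((logc - logc.mean()) ** 2))
        if ss_tot == 0:
            continue
        r2 = 1.0 - ss_res / ss_tot
        adj_r2 = 1.0 - (1.0 - r2) * (k - 1) / (k - 2)
        if best is None or adj_r2 > best[0] + 1e-12:
            best = (adj_r2, slope, k)
    if best is None:
        return None
    adj_r2, slope, k = best
    if slope >= 0 or adj_r2 < LAMBDA_Z_MIN_R2:
        return None
    return -slope, k, adj_r2


def run_nca(profile: ConcentrationTimeProfile) -> PKParameters:
    """Full NCA on a single-dose (or post-dose window) profile."""
    t = profile.times_h
    c = profile.conc_ng_per_ml
    if len(t) < 2:
        raise ValueError("NCA requires at least two concentration-time points")
    i_max = int(np.argmax(c))
    cmax, tmax = float(c[i_max]), float(t[i_max])
    auc_t = auc_trapezoid(t, c)
    fit = _fit_lambda_z(t, c)
    if fit is None:
        logger.info("lambda_z not estimable; AUC(0-inf) flagged missing")
        return PKParameters(
            cmax_ng_per_ml=cmax, tmax_h=tmax, auc_0_t_ng_h_per_ml=auc_t
        )
    lz, k, adj_r2 = fit
    c_last = float(c[c > 0][-1]) if np.any(c > 0) else 0.0
    auc_inf = auc_t + c_last / lz
    return PKParameters(
        cmax_ng_per_ml=cmax,
        tmax_h=tmax,
        auc_0_t_ng_h_per_ml=auc_t,
        auc_0_inf_ng_h_per_ml=auc_inf,
        lambda_z_per_h=lz,
        t_half_h=math.log(2.0) / lz,
        extrapolated_fraction=(auc_inf - auc_t) / auc_inf if auc_inf > 0 else None,
        n_lambda_z_points=k,
        lambda_z_adj_r2=adj_r2,
    )


def steady_state_auc_tau(profile: ConcentrationTimeProfile, t_start: float, t_end: float) -> float:
    """AUC over one dosing interval [t_start, t_end] of a multiple-dose profile."""
    mask = (profile.times_h >= t_start - 1e-9) & (profile.times_h <= t_end + 1e-9)
    if mask.sum() < 2:
        raise ValueError("interval contains fewer than two grid points")
    return auc_trapezoid(profile.times_h[mask], profile.conc_ng_per_ml[mask])


def average_fold_error(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """AFE = 10^mean(log10(pred/obs)); 1 means unbiased in log space.

    Pairs with a non-positive member are excluded (count logged).
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("predicted and observed must be paired (same length)")
    mask = (pred > 0) & (obs > 0)
    excluded = int((~mask).sum())
    if excluded:
        logger.info("AFE: excluded %d non-positive pairs", excluded)
    if mask.sum() == 0:
        raise ValueError("no positive predicted/observed pairs")
    return float(10.0 ** np.mean(np.log10(pred[mask] / obs[mask])))


def fold_change(pk_special: PKParameters, pk_reference: PKParameters) -> Tuple[float, float]:
    """(AUC ratio, Cmax ratio) of a special population vs the reference."""
    ref_auc = pk_reference.auc_0_inf_ng_h_per_ml or pk_reference.auc_0_t_ng_h_per_ml
    sp_auc = pk_special.auc_0_inf_ng_h_per_ml or pk_special.auc_0_t_ng_h_per_ml
    if not ref_auc or ref_auc <= 0:
        raise ValueError("reference AUC must be positive")
    return sp_auc / ref_auc, pk_special.cmax_ng_per_ml / pk_reference.cmax_ng_per_ml


def recommend_dose_fraction_from_ratio(auc_ratio: float) -> int:
    """Dose fraction (%) that matches reference exposure, from an AUC ratio."""
    if auc_ratio <= 0:
        raise ValueError("AUC ratio must be positive")
    return round_half_up(100.0 / auc_ratio)


def recommend_dose_fraction(auc_reference: float, auc_special: float) -> int:
    """Dose fraction (%) = round(100 * AUC_ref / AUC_special), half-up."""
    if auc_reference <= 0 or auc_special <= 0:
        raise ValueError("AUC values must be positive")
    return recommend_dose_fraction_from_ratio(auc_special / auc_reference)


def dose_recommendation(
    label: str,
    auc_reference: float,
    auc_special: float,
    cmax_reference: Optional[float] = None,
    cmax_special: Optional[float] = None,
) -> DoseRecommendation:
    return DoseRecommendation(
        population_label=label,
        auc_ratio_vs_reference=auc_special / auc_reference,
        cmax_ratio_vs_reference=(
            cmax_special / cmax_reference if cmax_reference and cmax_special else None
        ),
        dose_fraction_percent=recommend_dose_fraction(auc_reference, auc_special),
    )
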