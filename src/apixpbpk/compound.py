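"""Drug-specific parameters, tissue partitioning and clearance terms.

Apixaban is treated as effectively neutral at physiological pH (acidic pKa
13.07), so both partition-coefficient methods use the un-ionized species
only.  Hepatic elimination is the lumped plasma clearance CL_H applied to
the liver plasma-equivalent concentration; renal plasma clearance follows
the glomerular-filtration relation CL_R = f_GFR * fu * GFR.
"""
from __future__ import annotations

import warnings
from importlib import resources
from typing import Dict, Literal

import yaml
from pydantic import BaseModel, Field, model_validator

from .physiology import PhysiologyParameters

KpMethod = Literal["pksim_standard_like", "rodgers_rowland"]
SUPPORTED_KP_METHODS = ("pksim_standard_like", "rodgers_rowland")


class CompoundParameters(BaseModel):
    """Physicochemical, permeability and clearance inputs for one compound."""

    name: str = "compound"
    log_p: float
    fu_plasma: float = Field(gt=0, le=1)
    mw_g_per_mol: float = Field(gt=0)
    pka_acid: float = 13.07
    peff_cm_per_min: float = Field(gt=0)
    cl_h_l_per_h: float = Field(ge=0)
    f_gfr: float = Field(ge=0)
    blood_plasma_ratio: float = Field(default=1.0, gt=0)

    @model_validator(mode="after")
    def _warn_f_gfr(self) -> "CompoundParameters":
        if self.f_gfr > 1:
            warnings.warn(
                f"f_gfr = {self.f_gfr} exceeds 1 (net tubular secretion implied)",
                stacklevel=2,
            )
        return self


class PartitionCoefficients(BaseModel):
    """Tissue:plasma partition coefficients for every perfused organ."""

    kp: Dict[str, float]
    method: KpMethod

    @model_validator(mode="after")
    def _check(self) -> "PartitionCoefficients":
        bad = {k: v for k, v in self.kp.items() if not v > 0}
        if bad:
            raise ValueError(f"all Kp must be > 0, got {bad}")
        if "rest" not in self.kp:
            raise ValueError("Kp for 'rest' compartment must be defined")
        return self


def load_compound(path) -> CompoundParameters:
    """Read a flat YAML compound parameter file."""
    with open(path) as fh:
        return CompoundParameters(**yaml.safe_load(fh))


def apixaban() -> CompoundParameters:
    """The packaged apixaban parameter set."""
    text = resources.files("apixpbpk.data").joinpath("apixaban.yaml").read_text()
    return CompoundParameters(**yaml.safe_load(text))


# Tissue composition: fractional volumes (water, neutral lipid, phospholipid)
# per mL tissue, standard human values compiled from the tissue-composition
# literature used by perfusion-limited PBPK partition methods.
TISSUE_COMPOSITION: Dict[str, tuple] = {
    "lung": (0.811, 0.0030, 0.0090),
    "heart": (0.758, 0.0115, 0.0166),
    "brain": (0.770, 0.0510, 0.0565),
    "muscle": (0.760, 0.0238, 0.0072),
    "adipose": (0.180, 0.7900, 0.0020),
    "skin": (0.718, 0.0284, 0.0111),
    "bone": (0.439, 0.0740, 0.0011),
    "liver": (0.751, 0.0348, 0.0252),
    "kidney": (0.783, 0.0207, 0.0162),
    "spleen": (0.788, 0.0201, 0.0198),
    "pancreas": (0.664, 0.0403, 0.0090),
    "stomach": (0.718, 0.0487, 0.0163),
    "small_intestine": (0.718, 0.0487, 0.0163),
    "large_intestine": (0.718, 0.0487, 0.0163),
    "gonads": (0.799, 0.0066, 0.0037),
    # muscle-like average for the unassigned remainder
    "rest": (0.770, 0.0200, 0.0100),
}
PLASMA_COMPOSITION = (0.945, 0.0023, 0.0013)


def _fu_tissue(fu: float) -> float:
    # tissue binding assumed half as strong as plasma binding (interstitial
    # protein dilution), the convention of composition-based Kp methods
    return 1.0 / (1.0 + 0.5 * (1.0 - fu) / fu)


def compute_partition_coefficients(
    cmp: CompoundParameters,
    phys: PhysiologyParameters,
    method: KpMethod = "pksim_standard_like",
) -> PartitionCoefficients:
    """Composition-based tissue:plasma partition coefficients.

    ``pksim_standard_like`` partitions into neutral lipid (octanol-scaled,
    vegetable-oil-scaled for adipose), phospholipid (30% lipid-like / 70%
    water-like) and water, corrected by the plasma:tissue unbound-fraction
    ratio.  ``rodgers_rowland`` is the simplified neutral-species variant
    Kp = fu * (f_w + P*f_nl + (0.3P+0.7)*f_np).
    """
    if method not in SUPPORTED_KP_METHODS:
        raise ValueError(
            f"unknown Kp method {method!r}; supported: {list(SUPPORTED_KP_METHODS)}"
        )
    p_oct = 10.0 ** cmp.log_p
    d_vow = 10.0 ** (1.115 * cmp.log_p - 1.35)  # vegetable oil:water
    fw_p, fnl_p, fnp_p = PLASMA_COMPOSITION
    fu = cmp.fu_plasma
    fut = _fu_tissue(fu)
    kp: Dict[str, float] = {}
    for organ, (fw, fnl, fnp) in TISSUE_COMPOSITION.items():
        if method == "pksim_standard_like":
            p = d_vow if organ == "adipose" else p_oct
            num = p * (fnl + 0.3 * fnp) + (fw + 0.7 * fnp)
            den = p * (fnl_p + 0.3 * fnp_p) + (fw_p + 0.7 * fnp_p)
            fu_ratio = fu if organ == "adipose" else fu / fut
            kp[organ] = num / den * fu_ratio
        else:  # rodgers_rowland
            kpu = fw + p_oct * fnl + (0.3 * p_oct + 0.7) * fnp
            kp[organ] = fu * kpu
    return PartitionCoefficients(kp=kp, method=method)


def renal_plasma_clearance(cmp: CompoundParameters, phys: PhysiologyParameters) -> float:
    """CL_R (L/h) = f_GFR * fu * GFR, with GFR converted mL/min -> L/h."""
    gfr_l_per_h = phys.gfr_ml_per_min * 60.0 / 1000.0
    return cmp.f_gfr * cmp.fu_plasma * gfr_l_per_h


def f_gfr_from_clearance(cl_r_l_per_h: float, fu: float, gfr_ml_per_min: float) -> float:
    """Invert the filtration relation: f_GFR = CL_R / (fu * GFR)."""
    if gfr_ml_per_min <= 0:
        raise ValueError("GFR must be positive")
    return cl_r_l_per_h / (fu * gfr_ml_per_min * 60.0 / 1000.0)


def scale_fu_for_binding(cmp: CompoundParameters, albumin_ontogeny: float) -> float:
    """Unbound fraction after scaling binding-protein abundance.

    With binding capacity proportional to the ontogeny factor,
    fu' = 1 / (1 + ontogeny * (1-fu)/fu); identity at ontogeny 1, rising
    toward 1 as the binding protein disappears.
    """
    if albumin_ontogeny <= 0:
        raise ValueError("albumin_ontogeny must be > 0")
    fu = cmp.fu_plasma
    return 1.0 / (1.0 + albumin_ontogeny * (1.0 - fu) / fu)
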