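# Methods

## Scope and model structure

`apixpbpk` simulates the plasma pharmacokinetics of oral apixaban — a
narrow-therapeutic-index direct factor Xa inhibitor — in healthy adults and
in three special populations (renal impairment graded by creatinine
clearance, Child-Pugh hepatic impairment, and the elderly), and turns the
resulting exposures into fold-change tables and dose-fraction
recommendations.

The disposition model is a whole-body, perfusion-limited (flow-limited)
compartment system with 18 anatomical compartments: lung, heart, brain,
muscle, adipose, skin, bone, liver, kidney, spleen, pancreas, stomach,
small intestine, large intestine, gonads, a lumped "rest" compartment that
closes mass and flow totals, and arterial/venous blood pools.  Splanchnic
organs drain through the portal vein into the liver.  For every tissue the
mass balance is

    V_t dC_t/dt = Q_t (C_art − C_t / Kp_t),

with the liver receiving hepatic arterial plus portal inflow.  Elimination
is (i) the lumped hepatic plasma clearance CL_H applied to the liver
plasma-equivalent concentration C_liver/Kp_liver — no well-stirred
intrinsic-clearance back-calculation, because only the lumped value is an
input — and (ii) renal clearance by glomerular filtration,
CL_R = f_GFR · fu · GFR, applied to the kidney plasma-equivalent
concentration.  The blood:plasma ratio defaults to 1 and the equations are
written against plasma concentrations.

Oral absorption uses three sequential GI lumen transit compartments
(stomach → small intestine → large intestine → feces) with first-order
transit (stomach-emptying half-life 0.25 h; mean small-intestinal transit
3.3 h; colonic transit 13.5 h).  Uptake is a permeability-limited flux from
the small-intestinal lumen into the portal stream:
Peff × (effective mucosal area) × C_lumen.  The single calibrated constant
is a multiplier on the effective area (default base area 2×10⁶ cm²,
multiplier 1), fitted "middle-out" to low-dose concentration data by
minimizing squared log-concentration error.  No solubility limit is
modeled; apixaban doses here are small and only the immediate-release
formulation is considered.

The whole system is linear and time-invariant, so dose proportionality and
superposition hold exactly up to solver error; the suite asserts both, plus
mass conservation (every column of the rate matrix sums to zero, checked at
build time, and the integrated balance is verified to 0.1% of dose).

## Key parameters

| Parameter | Value | Units | Note |
|---|---|---|---|
| log P | 2.22 | – | lipophilicity |
| fu (plasma) | 0.93 | – | model input as packaged; see limitations |
| MW | 459 | g/mol | |
| pKa (acid) | 13.07 | – | effectively neutral at physiological pH |
| Peff | 9×10⁻⁷ | cm/min | specific intestinal permeability |
| CL_H | 2.4 | L/h | lumped hepatic plasma clearance |
| f_GFR | 0.18 | – | glomerular filtration fraction |
| GFR (healthy adult) | 120 | mL/min | reference creatinine clearance |
| Hematocrit (healthy) | 0.47 | – | |
| Hepatic arterial flow | 0.44 | L/min | healthy baseline |
| Renal blood flow | 1.35 | L/min | healthy baseline |
| Liver volume | 2.44 | L | healthy baseline |

The reference individual is a 30-year-old, 82 kg, 180 cm male
(BMI 25.31 kg/m²).  Remaining organ volumes and blood flows come from a
documented reference-human table (ICRP Publication 89, rescaled) with the
hepatic/renal entries pinned to the values above; volumes scale linearly
with body weight and flows with weight^0.75, so the reference reproduces
the pinned values exactly.  Named demographic presets (`european_adult`,
`chinese_adult`, `chinese_elderly`) differ only in mean body size; the
Chinese anthropometrics are implementer-documented means, not taken from
any clinical table.

## Tissue partitioning

"Standard" PBPK software partition methods are proprietary, so the package
implements two published-style composition-based methods selected by a
`method` argument:

* `pksim_standard_like` (default): a Poulin–Theil-type calculation over
  fractional tissue water, neutral lipid and phospholipid, using the
  octanol–water partition coefficient for lean tissues and the
  vegetable-oil correlation log D_vo = 1.115·log P − 1.35 for adipose, with
  the plasma:tissue unbound-fraction correction
  fu_t = 1/(1 + 0.5·(1−fu)/fu).
* `rodgers_rowland`: the simplified neutral-species variant
  Kp = fu · (f_w + P·f_nl + (0.3P + 0.7)·f_np).

Both satisfy the tested invariants: Kp > 0 everywhere, adipose Kp monotone
in log P, Kp_adipose > Kp_muscle for apixaban, and the stated closed-form
fu dependence.

## Special-population overlays

**Renal impairment** is parameterized by creatinine clearance
(normal/mild/moderate/severe = 120/65/40/15 mL/min).  The individual's GFR
is multiplied by CLcr_i/CLcr_ref, which makes the filtration relation and
the linear clearance-ratio relation CL_R,i = CL_R,ref · CLcr_i/CLcr_ref
mutually consistent by construction.  Nothing else changes.

**Hepatic impairment** applies the Child-Pugh overlay exactly as printed:

| Parameter | Healthy | CP-A | CP-B | CP-C |
|---|---|---|---|---|
| Hepatic blood flow (L/min) | 0.44 | 0.45 | 0.79 | 0.15 |
| Renal blood flow (L/min) | 1.35 | 0.94 | 0.69 | 0.51 |
| Other organs (× healthy flow) | 1 | 1.75 | 2.25 | 2.75 |
| Liver volume (L) | 2.44 | 1.32 | 1.05 | 0.53 |
| Hematocrit | 0.47 | 0.39 | 0.37 | 0.35 |
| Albumin ontogeny | 1 | 0.81 | 0.68 | 0.5 |
| AGP ontogeny | 1 | 0.6 | 0.56 | 0.3 |

"Other organs" multiplies the blood flow of every tissue except liver and
kidney; cardiac output is then recomputed so flow balance is restored.  The
unbound fraction is rescaled through the albumin ontogeny factor,
fu' = 1/(1 + ontogeny·(1−fu)/fu).  CL_H is held at its input value (an
optional per-class multiplier exists for sensitivity analysis).  One
design choice beyond the table: GFR is scaled with renal *plasma* flow
(constant filtration fraction), so the printed renal-flow decline carries
through to renal drug clearance — the hepatorenal component of cirrhosis.
Without this coupling the only clearance-relevant change in the overlay
would be the fu increase, which would (slightly) *lower* exposure with
increasing severity, contradicting the clinically observed direction.
The overlay demands a healthy baseline and refuses double application.
Note the CP-B hepatic flow (0.79 L/min) exceeds the healthy value as
printed in the source table; it is reproduced without reinterpretation.

**Elderly scaling** uses documented monotone decline functions: GFR
−0.75%/year past age 40; hepatic arterial flow −0.3%/year past 30; muscle
−0.6%/year and liver/kidney −0.3%/year past 30, with the lost lean volume
moved into adipose so body weight is conserved.  Scaling is the identity at
the adult baseline age and commutes with the renal overlay (both act
multiplicatively on disjoint or commuting parameters).

## NCA and reporting

AUC(0–t) is computed with the linear trapezoidal rule; λz by log-linear
regression over the last 3..10 post-peak points, selecting the window with
the best adjusted r² and requiring a negative slope and r² ≥ 0.8 (otherwise
AUC(0–∞) is flagged missing and AUC(0–t) still returned);
AUC(0–∞) = AUC(0–t) + C_last/λz.  Model fit is quantified by the average
fold error AFE = 10^mean(log10(pred/obs)) with non-positive pairs excluded;
the conventional acceptance band is 0.5–2.  Dose normalization reports
AUC/Cmax ratios to two decimals and the matching dose fraction as
round-half-up of 100·AUC_ref/AUC_special (equivalently 100/ratio — the two
entry points are exactly consistent because one calls the other).

## Synthetic data

The generator emulates the sparse digitized mean profiles the published
analysis was validated against: single doses 5/10/25/50 mg (n = 6),
b.i.d. 2.5/5/10/25 mg for 7 days, renal groups at CLcr 120/65/40/15 mL/min
(n = 8/10/7/7), hepatic groups healthy/CP-A/B/C (n = 16/8/8/8), and an
elderly cohort aged 60–81, 50% women (n = 12, chosen).  Each virtual
subject gets mean-preserving log-normal perturbations (CV 16% on organ
volumes/flows/GFR; 30% on CL_H and Peff), the group overlay, and
median-unbiased proportional log-normal residual noise (default CV 10%) at
8–14 sparse sampling times.  Because the noise has zero log-mean, fold-
error statistics against the generating model center on 1, which is what
the closure test (simulate → NCA → AFE ∈ [0.5, 2]) exploits.  What passing
closure does **not** show: agreement with real clinical profiles, which
would require the digitized observations themselves.

The parameter-recovery study plants a known absorption-area multiplier and
CL_H, generates a noisy 12-subject mean profile (residual noise only, so
all subjects share the planted values), and re-fits both by least squares
in log space; both recover within 10% at 10% noise.

## Numerical choices

* Stiff-capable LSODA integration with the analytic constant Jacobian,
  rtol 1e-8 / atol 1e-10; dosing as exact-time bolus events into the
  stomach lumen; a negative-state guard raises rather than silently clips.
* Default output grid 0.05 h for NCA stability; long-horizon runs
  (terminal-phase work) use 0.1 h.
* Simulation horizons are chosen relative to the model's terminal
  half-life: single-dose AUC(0–∞) and the steady-state identity use 720 h
  (≈ 8 terminal half-lives, extrapolated fraction < 1%), and the
  accumulation check uses 60 twice-daily doses.
* Ties in the λz window search resolve to the earliest (longest) window
  via strict improvement; regression uses `numpy.polyfit` on log
  concentrations.
* Degenerate inputs: zero dose yields an identically zero profile; a flat
  calibration target or zero-permeability start raises; single-point
  profiles are rejected by NCA.

## Known limitations

* The packaged unbound fraction (0.93) is reproduced verbatim from the
  model-input table it mirrors, but public references for apixaban report
  fu ≈ 0.13; with log P 2.22 the high fu inflates tissue partitioning,
  giving Vss of several hundred liters and a terminal half-life of ~3.6
  days instead of the clinical ~12 h.  AUC-based quantities are unaffected
  (AUC = F·D/CL), which is why the exposure-ratio and dose-fraction outputs
  remain meaningful; Cmax-based absolute values are not reliable.  The
  compound file accepts an fu override.
* Absolute printed exposures (e.g. adult AUC 2062 ng·h/mL) and the
  predicted impairment ratios of the source analysis depend on a
  proprietary population database and unprinted group covariates; the
  engine here is held to a 2-fold band on adult AUC and to the
  directional/ratio structure, and uses the printed exposures as *inputs*
  to dose normalization.
* Combined renal+hepatic impairment is mechanically possible (renal after
  hepatic is blocked only by the ontogeny guard in the other order) but
  unvalidated; pediatric scaling, dialysis, enterohepatic recirculation,
  transporters and food effects are out of scope.
* The elderly Cmax ratio computed from the printed exposures (254/189.5 =
  1.34) differs from the printed ratio 1.32; the package reports the
  computed value.
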