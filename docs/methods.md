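# Methods

## Scope and model structure

`gabapbpk` implements a reduced whole-body physiologically based
pharmacokinetic (PBPK) model of gabapentin and the analyses built on it:
qualification against published adult predicted/observed PK parameters,
extrapolation to renal impairment (RI) and pediatric age bands, local
sensitivity analysis, and renal-function-stratified dose adjustment.

Gabapentin is pharmacokinetically simple in one crucial respect: it is not
metabolized, is negligibly protein bound in the sense that matters for
clearance (fraction unbound in plasma fup = 0.73), and is eliminated
exclusively by the kidney through glomerular filtration plus active
tubular secretion. Plasma exposure is therefore governed almost entirely
by renal clearance; distribution detail beyond the steady-state volume of
distribution (Vss) has second-order influence on the plasma profile. That
is what justifies reducing the full commercial PBPK structure to an
11-compartment perfusion-limited model:

* gut lumen (absorption depot, not perfused),
* eight perfused tissues — gut, liver, kidney, muscle, adipose, skin,
  brain, rest-of-body — with `dA_t/dt = Q_t (C_art - C_t B:P / Kp_t)`,
* arterial and venous blood pools.

Oral dosing releases drug into the lumen (bolus for immediate release; a
constant rate over a stated duration for gastric-retentive
extended-release, default 6 h chosen so the single-dose peak falls in the
observed 5–8 h window). Absorption is first order with rate `ka`; the
absorbed fraction `fabs` enters the gut tissue and reaches the liver via
the portal flow. Saturable (LAT-transporter) absorption is deliberately
excluded: the reference predictions this package reproduces are exactly
dose-proportional, so a linear model is the faithful choice. `fabs` is
fixed at 1.0 — the identified renal clearance (3.2 mL/min/kg) is only
consistent with the reference single-dose AUC predictions
(~25.5 µg·h/mL per 300 mg in a 70 kg adult) under near-complete
absorption at modeled doses.

### Renal clearance

    CL_renal = fup · GFR_fraction · GFR_abs + fup · TSspec · ts_scale · V_kidney

with `TSspec = 0.74 min⁻¹` a specific (per-litre-of-kidney) secretion
rate, `ts_scale ∈ (0, 1]` the RI attenuation (1 when healthy), and the
total capped at kidney plasma flow for physical realizability (the cap is
far from binding at all modeled clearances). The elimination rate is
drawn from the kidney compartment but driven by the *arterial* plasma
concentration — filtration physically acts on afferent plasma — which
makes venous-plasma AUC0–∞ equal `fabs·Dose/CL` exactly for the full
model. The calibration chain below leans on that identity.

`GFR_abs = GFR_normalized · BSA/1.73 · m(age)`, with BSA by Du Bois
(0.007184·W^0.425·H^0.725) and `m(age)` a Hill-type maturation function
anchored at 0.30 at birth, ≥0.95 by age 2 (a50 = 0.5 y, Hill
coefficient 2), and exactly 1.0 from 18 y. Representative normalized GFR
values per renal class: 100 (normal), 30 (mild), 15 (moderate),
5 (severe) mL/min/1.73 m².

### Distribution

Per-organ tissue:plasma partition coefficients come from a deliberately
simple composition formula: tissue water plus neutral lipid weighted by
the zwitterion-corrected distribution coefficient at pH 7.4
(logD ≈ −2.44 from logP 0.52 and pKa 4.63 / 9.91 — gabapentin is almost
entirely ionized, so distribution is water-driven), ratioed against
plasma and multiplied by a single global scalar. The scalar is the
calibrated constant; fup does not enter the Kp formula (it drives
clearance only), which keeps the AUC identity above exact.

## Calibration chain

Every constant not given directly by the drug parameter table is pinned
by one observable consequence, solved in closed form at import time
(`gabapbpk.calibration`; re-derived and checked by
`analysis/01_calibrate_model.py`):

| constant | defining condition | value |
|---|---|---|
| effective kidney volume (70 kg adult) | total renal CL = 3.2 mL/min/kg | 0.2733 L |
| global Kp scalar | Vss = 0.8 L/kg (hydrophilic range, within the 0.5–1.0 L/kg plausibility band) | 1.368 |
| adult ts_scale (mild/mod/sev) | single-dose AUC folds vs healthy = 2.05 / 3.51 / 4.86 | 0.688 / 0.473 / 0.441 |
| pediatric ts_scale (mild/mod/sev) | exposure folds 2.0 / 3.30 / 31.67 at the 3–12 y representative | 0.763 / 0.555 / 0.0275 |
| ka | single-dose tmax = 2.5 h at 400 mg (bisection on the simulated model) | 0.45 h⁻¹ |

Kidney volume shrinks with RI severity by class multipliers
{1, 0.85, 0.75, 0.65}. The severe multiplier is 0.65 rather than a
rounder 0.6 because, under the exact adult fold calibration, 0.6 would
force the severe secretion scale above the moderate one; 0.65 preserves
strict monotonicity of GFR, kidney volume and ts_scale across classes.

Two pediatric choices deserve explanation:

* **Severe-RI secretion collapse.** The pediatric severe exposure fold
  (~32×) is far above the adult severe fold (4.86×) and is only
  reachable if proximal-tubular secretion is almost completely lost
  (ts_scale ≈ 0.028): at a representative GFR of 5 mL/min/1.73 m² the
  filtration route contributes ~2 mL/min in a school-age child, so the
  fold is set by how much secretion survives. The model treats the
  severely impaired developing kidney as having essentially no residual
  secretion capacity, while adult severe RI retains a substantial
  fraction — consistent with the observation that pediatric severe RI
  requires a qualitatively stronger dose reduction than adult severe RI.
* **Mild fold target 2.0 (reported ≈2.1).** The exposure-matching dose
  search switches its mild-RI answer from "full dose bid" to "full dose
  qd" when the exposure fold crosses √4.5 ≈ 2.12. Calibrating the
  3–12 y representative to 2.09 would put the 1 m–3 y band at ≈2.12 —
  on the knife edge — so the published recommendation pattern would not
  be stable across age bands. The mild secretion scale is instead set so
  the school-age fold is 2.0, keeping every band's fold in 1.93–2.03,
  safely inside the bid region, while remaining consistent with the
  reported ≈2-fold mild exposure rise.

Pediatric (<18 y) physiology otherwise scales organ volumes
proportionally to body weight and blood flows with weight^0.75; these are
standard, mass-consistent choices, not fits.

## Non-compartmental analysis

Cmax/tmax from the grid maximum; AUC by linear-up/log-down trapezoid;
terminal slope λz by log-linear regression over the trailing 3–6 points
after tmax (best adjusted r²), rejected — and the profile flagged — when
λz ≤ 0 or r² < 0.8; AUC0–∞ = AUC0–t + C_last/λz. Steady-state exposure
is reported per 24 h; an every-other-day (48 h) interval AUC is halved so
multi-regimen comparisons are like-for-like. These conventions shift AUC
by well under 1 % on the dense simulated grids used here.

## Qualification metrics

Per-pair fold error MFE = predicted/observed; cohort aggregates use the
arithmetic mean of the raw ratios. The geometric mean fold error is

    GMFE = 10^( mean |log10(predicted/observed)| )

— with the **absolute value**, so GMFE ≥ 1 measures typical fold distance
from the identity line. The signed variant (over/under-predictions
cancelling) is provided only as a diagnostic: on the adult development
AUC pairs it gives 1.03 where the absolute form gives the reported 1.18,
which is the evidence for the absolute-value reading. GMFE is always
computed from raw values, never from rounded per-pair MFEs (the packaged
table contains one per-pair entry, pediatric Cmax 1.60, that is
inconsistent with its own raw values 4.34/3.74 = 1.16; the cohort GMFE
confirms the raw reading). Acceptance: all MFE and GMFE below 2-fold.

The packaged reference table (`gabapbpk/data/pk_reference.csv`) carries
all predicted/observed triplets with cohort labels. The adult-evaluation
aggregate as printed (1.34) differs at the second decimal from
recomputation over its own rows (1.36) — evident rounding in the source —
so evaluation aggregates are tested to ±0.05 while the development, RI
and pediatric aggregates reproduce exactly to two decimals.

## Sensitivity analysis

Normalized local coefficients S = (ΔPK/PK)/(Δp/p), forward difference at
+10 % by default (central difference behind a flag). For this linear
model S(AUC; dose) = +1 exactly. Note that for reciprocal responses such
as AUC ∝ 1/fup the +10 % forward secant is −0.909 while the small-step
limit is −1; the 10 % and 1 % *forward* estimates therefore differ by
~0.08 by construction, and the convergence check in the test suite uses
the central difference, which does land within 0.05 of the small-step
estimate. fup is the dominant exposure parameter (S ≈ −0.91), ahead of
the two secretion determinants (ts_spec and kidney volume, ≈ −0.62
each) and GFR (≈ −0.33); absorption rate and partitioning do not move
AUC at all, as expected from AUC = F·D/CL.

## Dose recommendation

Reference exposure per age band is the labeled regimen: 5 mg/kg tid
below 12 y, 300 mg tid for 12–17 y and adults. Steady-state windows are
computed by periodic superposition of a single-dose simulation carried to
≥ 8 half-lives (exact for a linear model; verified against direct
multi-dose simulation to <1 %), which keeps the severe-RI scenarios
(half-life ~80 h in a school-age child) cheap.

The search mirrors the published adjustment principle as a two-stage
rule over the candidate grid {tid, bid, qd, qod} × {full, half dose}:

1. interval extension only — among full-dose schedules with steady-state
   AUC0–24h and Cmax ratios ≤ 2 vs reference, pick the one with AUC
   ratio closest to 1 in log space;
2. only if no full-dose schedule qualifies, admit the half-dose
   candidates; if nothing qualifies at all, return the closest candidate
   flagged best-effort (pediatric severe RI is such a case: the fold is
   so large that even 2.5 mg/kg qod sits ~2.6× above reference — the
   recommendation is the floor of the candidate grid, not an exposure
   match).

Ties (equal log distance within 10⁻³) prefer fewer daily
administrations. A single-stage "closest to 1 subject to ≤2" rule would
prefer halving the dose at unchanged frequency for mild RI (ratio
exactly 1 when the fold is ~2); the two-stage form encodes the stated
preference for prolonged intervals at the labeled per-dose amount, with
dose reduction reserved for severe impairment. Adult rows of the
published table reduce the absolute per-dose amount (300→200→100 mg),
which lies outside this grid; they are shipped as a lookup and excluded
from search-vs-rule agreement claims.

## Synthetic data

`gabapbpk.synthetic` generates "observed" profiles from closed-form one-
or two-compartment oral models with multiplicative log-normal residual
error (ε per sampling time, variance log(1+CV²)) and optional log-normal
inter-individual variability, seeded and bit-reproducible. The default
sampling grid mimics clinical PK sampling (0.25–48 h, denser near the
expected peak). What it deliberately does not emulate: assay LLOQ
censoring, below-quantification dropouts, sampling-time errors, and
model misspecification beyond the one- vs two-compartment choice — so
recovery tests demonstrate correctness of the NCA/metric pipeline, not
robustness to every feature of real bioanalytical data. At 10 % noise
the NCA-derived clearance median over 50 subjects recovers the truth
within 5 %; truth-vs-observed GMFE grows monotonically with noise and
matches the half-normal expectation 10^(σ√(2/π)/ln10) at large n.

## Numerical choices and problem sizes

* Integrator: LSODA, rtol 1e-8, atol 1e-10 µmol, output grid 0.05 h
  (0.1 h where only AUC matters); dosing via integration restarts, no
  Dirac approximations. Mass balance closes to ~1e-15 of dose.
* Single-dose horizons scale with severity (120–720 h) so the
  extrapolated AUC tail stays small even at pediatric-severe clearances.
* Validation targets use representative (median) individuals; the Monte
  Carlo population mode (log-normal weight/height variability around
  age-typical medians, seeded) exists for population simulations and is
  exercised at n = 10–200 in tests and examples.

## Known limitations

* Food effects, mechanistic gastro-retention, transporter saturation,
  IV dosing and hemodialysis are out of scope.
* The RI class scalings for kidney volume and secretion are calibrated
  stand-ins constrained by reported exposure folds, not measured organ
  data; the pediatric severe value in particular encodes an assumption
  (secretion collapse) that reproduces the reported fold pattern.
* Operative constants were taken where the source offered ranges
  (fup 0.73, logP 0.52, solubility 50 mg/mL); all are config-exposed.
* Representative-individual mode fixes GFR at the class-representative
  value; within-class GFR variability is not propagated into the
  validation targets.
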