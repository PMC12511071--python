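# gabapbpk

A reduced whole-body physiologically based pharmacokinetic (PBPK) analysis
of **gabapentin dosing in renal impairment and pediatrics**, for PK
modelers and clinical-pharmacology researchers who need a transparent,
fully scriptable alternative to closed-source PBPK platforms for this
drug's dosing questions.

Gabapentin is cleared exclusively by the kidney — unbound glomerular
filtration plus active tubular secretion — and is not metabolized, so its
plasma exposure is governed by renal clearance:

    CL_renal = fup · GFR_abs + fup · TSspec · ts_scale · V_kidney

An 11-compartment perfusion-limited model (gut lumen, eight perfused
tissues, arterial/venous blood) with first-order oral absorption is driven
by virtual individuals whose physiology scales with age, body size and
renal-function class (representative GFR 100 / 30 / 15 / 5
mL/min/1.73 m² for normal / mild / moderate / severe impairment, with a
Hill-type GFR maturation function for children). Model qualification uses
the geometric mean fold error over predicted/observed PK-parameter pairs,

    GMFE = 10^( mean |log10(pred/obs)| ),

with the conventional 2-fold acceptance bound, and the dose-adjustment
analysis matches steady-state 24 h exposure (AUC0–24h) across renal
classes by extending the dosing interval (tid → bid → qd → qod) and, for
severe impairment, halving the dose.

See `docs/methods.md` for the model, its assumptions and the calibration
chain.

## Layout

```
src/gabapbpk/        library: physiology, engine, nca, validation,
                     sensitivity, dosing, synthetic, calibration
analysis/            numbered narrative scripts (01 calibration ...
                     07 synthetic recovery); write tables to results/
scripts/acceptance.py  recomputes the headline numbers (below)
tests/               pytest suite
```

## Worked example

Simulate a 400 mg single oral dose in the representative healthy adult,
run non-compartmental analysis, and qualify the engine against the
packaged adult observed values:

```python
from gabapbpk import GABAPENTIN, Regimen, simulate, nca_single_dose
from gabapbpk.physiology import representative_individual
from gabapbpk.workflows import adult_development_validation

adult = representative_individual("adult")
ts = simulate(adult, GABAPENTIN, Regimen.single(400.0, 48.0))
pk = nca_single_dose(ts)
print(f"AUC0-inf {pk.auc_0_inf:.2f} ug*h/mL  Cmax {pk.cmax:.2f} ug/mL  tmax {pk.tmax:.2f} h")

for param, s in adult_development_validation().items():
    print(f"{param:9s} GMFE {s.gmfe:.2f}  within 2-fold {s.fold_fractions[2.0]:.0%}")
```

prints

```
AUC0-inf 29.76 ug*h/mL  Cmax 3.36 ug/mL  tmax 2.50 h
auc_0_inf GMFE 1.11  within 2-fold 100%
cmax      GMFE 1.11  within 2-fold 100%
tmax      GMFE 1.32  within 2-fold 100%
```

The AUC equals dose/clearance (400 mg / 13.44 L/h) because the model has
no non-renal elimination; every GMFE is comfortably below the 2-fold
qualification bound. Running `python analysis/06_dose_recommendations.py`
then reproduces the published pediatric dose-adjustment table in all
12 age-band × renal-class cells from the exposure-matching search, e.g.
for school-age children: 5 mg/kg tid (normal) → 5 mg/kg bid (mild) →
5 mg/kg qd (moderate) → 2.5 mg/kg qod (severe).

Scenario files are supported for scripted runs (`gabapbpk.scenarios`;
see `examples/adult_400mg.yaml`).

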