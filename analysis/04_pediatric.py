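#!/usr/bin/env python
"""Pediatric extrapolation: age-band exposures and RI fold-changes.

Checks that weight-based dosing (5 mg/kg) produces similar exposure in the
1 m-3 y and 3-12 y bands, and quantifies the exposure rise with renal
impairment at the labeled 5 mg/kg tid regimen for each pediatric band.
"""

from pathlib import Path

import pandas as pd

from gabapbpk.dosing import steady_state_window
from gabapbpk.engine import GABAPENTIN, REGIMEN_INTERVALS
from gabapbpk.physiology import representative_individual
from gabapbpk.workflows import ri_auc_folds, single_dose_auc

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main():
    print("single 10 mg/kg dose, healthy (weight-based dosing equivalence):")
    for band in ("1m-3y", "3-12y"):
        auc = single_dose_auc(band, "normal", dose_mg_per_kg=10.0, duration=120.0)
        print(f"  {band:7s} AUC0-inf {auc:6.2f} ug*h/mL")

    rows = []
    for band in ("1m-3y", "3-12y", "12-17y"):
        dose_kw = {"dose_mg_per_kg": 5.0} if band != "12-17y" else {"dose_mg": 300.0}
        folds = ri_auc_folds(band, **dose_kw)
        print(f"\n{band}: AUC0-inf fold vs healthy at the labeled regimen")
        for cls, fold in folds.items():
            print(f"  {cls:9s} {fold:6.2f}")
            rows.append(dict(age_band=band, renal_class=cls, auc_fold=fold))

    # steady-state exposure at the unadjusted labeled regimen (3-12 y)
    print("\n3-12 y steady-state AUC0-24h at unadjusted 5 mg/kg tid:")
    ref = None
    for cls in ("normal", "mild", "moderate", "severe"):
        ind = representative_individual("3-12y", cls)
        pk = steady_state_window(ind, GABAPENTIN, 5.0 * ind.demographics.weight,
                                 REGIMEN_INTERVALS["tid"])
        ref = ref or pk.auc_0_24
        print(f"  {cls:9s} AUC0-24h {pk.auc_0_24:7.1f} ug*h/mL  "
              f"({pk.auc_0_24/ref:5.2f}x healthy)")

    pd.DataFrame(rows).to_csv(OUT / "pediatric_ri_folds.csv", index=False)
    print(f"\nwrote {OUT/'pediatric_ri_folds.csv'}")


if __name__ == "__main__":
    main()
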