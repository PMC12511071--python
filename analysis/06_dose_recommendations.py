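#!/usr/bin/env python
"""Renal-function-stratified dose recommendations.

Runs the exposure-matching search for every age band and renal class and
compares it with the published rule table; reports the steady-state
exposure ratios that justify each recommendation.
"""

from pathlib import Path

import pandas as pd

from gabapbpk.dosing import rule_based_recommendation, search_recommendation
from gabapbpk.physiology import AGE_BANDS

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main():
    rows = []
    for band in AGE_BANDS:
        for cls in ("normal", "mild", "moderate", "severe"):
            rec = search_recommendation(band, cls)
            rule = rule_based_recommendation(band, cls)
            agree = rec.regimen_tuple == rule.regimen_tuple
            m = rec.rationale_metrics
            rows.append(dict(
                age_band=band, renal_class=cls,
                search=f"{rec.per_dose:g} {rec.unit} {rec.frequency}",
                rule=f"{rule.per_dose:g} {rule.unit} {rule.frequency}",
                agree=agree, feasible=rec.feasible,
                ratio_auc24=m["ratio_auc24"], ratio_cmax=m["ratio_cmax"],
            ))
            mark = "==" if agree else "!="
            flag = "" if rec.feasible else "  [best-effort: >2-fold floor]"
            print(f"{band:7s} {cls:9s} search {rows[-1]['search']:16s} {mark} "
                  f"rule {rows[-1]['rule']:16s} AUC ratio {m['ratio_auc24']:5.2f}{flag}")

    df = pd.DataFrame(rows)
    ped = df[df.age_band != "adult"]
    print(f"\npediatric agreement: {ped.agree.sum()}/{len(ped)} cells")
    print("(adult rows use absolute per-dose reductions outside the search grid)")
    df.to_csv(OUT / "dose_recommendations.csv", index=False)
    print(f"wrote {OUT/'dose_recommendations.csv'}")


if __name__ == "__main__":
    main()
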