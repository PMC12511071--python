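#!/usr/bin/env python
"""Local sensitivity screen of the healthy-adult model.

One-at-a-time +10% perturbations of the key drug/physiology parameters,
reporting normalized coefficients for systemic exposure (AUC0-inf) and
peak concentration (Cmax).
"""

import json
from pathlib import Path

from gabapbpk.engine import GABAPENTIN, Regimen
from gabapbpk.physiology import representative_individual
from gabapbpk.sensitivity import EngineScenario, sensitivity_screen

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

PARAMS = ["fup", "ka", "ts_spec", "kidney_volume", "kp_scale", "gfr", "dose"]


def main():
    scen = EngineScenario(
        representative_individual("adult"), GABAPENTIN, Regimen.single(400.0, 48.0)
    )
    report = {}
    for output in ("auc_0_inf", "cmax"):
        ranked = sensitivity_screen(scen, PARAMS, output)
        print(f"\nsensitivity of {output} (+10% forward difference):")
        for r in ranked:
            print(f"  {r.parameter_name:14s} S = {r.coefficient:+6.3f}")
        report[output] = {r.parameter_name: r.coefficient for r in ranked}
    (OUT / "sensitivity.json").write_text(json.dumps(report, indent=2))
    print(f"\nwrote {OUT/'sensitivity.json'}")


if __name__ == "__main__":
    main()
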