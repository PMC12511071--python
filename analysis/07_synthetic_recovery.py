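#!/usr/bin/env python
"""Synthetic-data validation of the NCA / qualification pipeline.

Generates noisy one-compartment "observed" profiles with known truth,
checks that NCA recovers the generating clearance, and shows how the
GMFE of truth-vs-observed pairs grows with the injected residual noise.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from gabapbpk.nca import nca_single_dose
from gabapbpk.synthetic import SyntheticStudySpec, generate_profiles, make_predobs_table
from gabapbpk.validation import gmfe

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    args = ap.parse_args()

    truth = {"CL": 10.0, "V": 50.0, "ka": 1.0, "F": 1.0}
    spec = SyntheticStudySpec(truth_params=truth, noise_cv=0.10, n_subjects=50,
                              seed=args.seed)
    profiles, _ = generate_profiles(spec)
    results = [nca_single_dose(p) for p in profiles]
    cl_hat = [400.0 / r.auc_0_inf for r in results if r.valid_terminal_phase]
    print(f"CL recovery at 10% noise: median {np.median(cl_hat):.2f} L/h "
          f"(truth {truth['CL']}), {len(cl_hat)}/{len(profiles)} evaluable")

    noise_curve = {}
    truth_pk = nca_single_dose(generate_profiles(
        SyntheticStudySpec(truth_params=truth, noise_cv=0.0))[0][0])
    for cv in (0.0, 0.05, 0.10, 0.20):
        spec = SyntheticStudySpec(truth_params=truth, noise_cv=cv, n_subjects=40,
                                  seed=args.seed + int(cv * 100))
        profs, _ = generate_profiles(spec)
        obs = {f"s{i}": nca_single_dose(p) for i, p in enumerate(profs)}
        pred = {k: truth_pk for k in obs}
        pairs = make_predobs_table(pred, obs, parameters=("auc_0_inf", "cmax"))
        noise_curve[cv] = gmfe(pairs)
        print(f"  noise CV {cv:4.0%} -> truth-vs-observed GMFE {noise_curve[cv]:.3f}")

    (OUT / "synthetic_recovery.json").write_text(json.dumps(
        {"cl_median": float(np.median(cl_hat)), "cl_truth": truth["CL"],
         "n_evaluable": len(cl_hat), "gmfe_vs_noise": noise_curve}, indent=2))
    print(f"wrote {OUT/'synthetic_recovery.json'}")


if __name__ == "__main__":
    main()
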