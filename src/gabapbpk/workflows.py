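"""End-to-end computations shared by the analysis scripts and tests."""

from __future__ import annotations

from typing import Dict, Optional

from .engine import DrugParams, GABAPENTIN, Regimen, simulate
from .nca import nca_single_dose
from .physiology import representative_individual
from .validation import ValidationSummary, validate_engine

__all__ = [
    "DEV_SINGLE_DOSES_MG",
    "adult_development_predictions",
    "adult_development_validation",
    "single_dose_auc",
    "ri_auc_folds",
]

#: Single oral doses of the adult model-development studies (mg).
DEV_SINGLE_DOSES_MG = (300.0, 400.0, 600.0)


def adult_development_predictions(
    drug: DrugParams = GABAPENTIN, dt: float = 0.05
) -> Dict[str, Dict[str, float]]:
    """Engine PK predictions for the single-dose development regimens."""
    ind = representative_individual("adult")
    out: Dict[str, Dict[str, float]] = {}
    for dose in DEV_SINGLE_DOSES_MG:
        ts = simulate(ind, drug, Regimen.single(dose, 48.0), dt=dt)
        pk = nca_single_dose(ts)
        out[f"single_{int(dose)}"] = {
            "auc_0_inf": pk.auc_0_inf,
            "cmax": pk.cmax,
            "tmax": pk.tmax,
        }
    return out


def adult_development_validation(
    drug: DrugParams = GABAPENTIN, dt: float = 0.05
) -> Dict[str, ValidationSummary]:
    """Engine vs observed development-cohort PK parameters."""
    return validate_engine(adult_development_predictions(drug, dt), "adult_dev")


def single_dose_auc(
    age_band: str,
    renal_class: str,
    dose_mg: Optional[float] = None,
    dose_mg_per_kg: Optional[float] = None,
    duration: float = 240.0,
    dt: float = 0.05,
    drug: DrugParams = GABAPENTIN,
) -> float:
    """AUC0-inf of a representative individual after one oral dose."""
    ind = representative_individual(age_band, renal_class)
    if dose_mg is None:
        if dose_mg_per_kg is None:
            raise ValueError("give dose_mg or dose_mg_per_kg")
        dose_mg = dose_mg_per_kg * ind.demographics.weight
    ts = simulate(ind, drug, Regimen.single(dose_mg, duration), dt=dt)
    pk = nca_single_dose(ts)
    return pk.auc_0_inf


def ri_auc_folds(
    age_band: str,
    dose_mg: Optional[float] = None,
    dose_mg_per_kg: Optional[float] = None,
    dt: float = 0.05,
    drug: DrugParams = GABAPENTIN,
) -> Dict[str, float]:
    """Single-dose AUC0-inf fold-change vs healthy per RI class.

    Simulation horizons grow with severity so the extrapolated AUC tail
    stays small even at the slowest pediatric severe clearances.
    """
    durations = {"normal": 120.0, "mild": 240.0, "moderate": 360.0, "severe": 720.0}
    auc = {
        cls: single_dose_auc(age_band, cls, dose_mg, dose_mg_per_kg, dur, dt, drug)
        for cls, dur in durations.items()
    }
    return {cls: auc[cls] / auc["normal"] for cls in ("mild", "moderate", "severe")}
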