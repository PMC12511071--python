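"""Scenario configuration (YAML/JSON) and tabular export helpers."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml

from . import calibration
from .engine import DrugParams, GABAPENTIN, Regimen
from .physiology import (
    Demographics,
    VirtualIndividual,
    build_individual,
    representative_individual,
    sample_population,
)

__all__ = ["load_scenario", "drug_from_config", "population_to_csv", "timeseries_to_csv"]

_DRUG_KEYS = {
    "logP": "logp",
    "pKa_acid": "pka_acid",
    "pKa_base": "pka_base",
    "MW": "mw",
    "solubility": "solubility_ph7",
    "fup": "fup",
    "B2P": "b2p",
    "GFR_fraction": "gfr_fraction",
    "TS_spec": "ts_spec",
    "CL_renal_ref": "cl_renal_ref",
    "ka": "ka",
    "fabs": "fabs",
    "kp_scale": "kp_scale",
}


def drug_from_config(block: Optional[Dict]) -> DrugParams:
    """DrugParams from a config block; unspecified keys keep the defaults."""
    if not block:
        return GABAPENTIN
    unknown = set(block) - set(_DRUG_KEYS)
    if unknown:
        raise ValueError(f"unknown drug keys: {sorted(unknown)}")
    kwargs = {field: float(block[key]) for key, field in _DRUG_KEYS.items() if key in block}
    base = asdict(GABAPENTIN)
    base.update(kwargs)
    return DrugParams(**base)


def _regimen_from_config(block: Dict, weight: float) -> Regimen:
    if "dose_mg" in block:
        dose = float(block["dose_mg"])
    elif "dose_mg_per_kg" in block:
        dose = float(block["dose_mg_per_kg"]) * weight
    else:
        raise ValueError("regimen block needs dose_mg or dose_mg_per_kg")
    frequency = block.get("frequency", "single")
    formulation = block.get("formulation", "IR")
    release = "immediate" if formulation == "IR" else "zero_order"
    release_duration = float(block.get("release_duration_h", 6.0)) if release == "zero_order" else 0.0
    if frequency == "single":
        duration = float(block.get("days", 2)) * 24.0
        return Regimen.single(dose, duration, release, release_duration)
    days = float(block.get("days", 7))
    return Regimen.repeated(frequency, dose, days, release, release_duration)


def load_scenario(path: str | Path) -> Dict:
    """Parse a scenario file into model objects.

    Returns a dict with keys ``drug`` (DrugParams), ``individuals``
    (list of VirtualIndividual) and ``regimen`` (Regimen). The individual
    block either names an age band (representative mode) or gives explicit
    demographics, or a population block requests Monte Carlo sampling.
    """
    path = Path(path)
    with path.open() as fh:
        cfg = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)

    drug = drug_from_config(cfg.get("drug"))
    renal_class = cfg.get("renal_class", "normal")

    individuals: List[VirtualIndividual]
    if "population" in cfg:
        pop = cfg["population"]
        individuals = sample_population(
            n=int(pop["n"]),
            age_range=(float(pop["age_min"]), float(pop["age_max"])),
            renal_class=renal_class,
            seed=int(pop.get("seed", 0)),
        )
    elif "individual" in cfg:
        ind = cfg["individual"]
        if "age_band" in ind:
            individuals = [representative_individual(ind["age_band"], renal_class)]
        else:
            demo = Demographics(
                age=float(ind["age"]),
                weight=float(ind["weight"]),
                height=float(ind["height"]),
                sex=ind.get("sex", "male"),
            )
            individuals = [build_individual(demo, renal_class)]
    else:
        raise ValueError("scenario needs an 'individual' or 'population' block")

    regimen = _regimen_from_config(cfg["regimen"], individuals[0].demographics.weight)
    return {"drug": drug, "individuals": individuals, "regimen": regimen}


def population_to_csv(individuals: Sequence[VirtualIndividual], path: str | Path) -> pd.DataFrame:
    """One row per individual: demographics plus derived physiology."""
    rows = []
    for i, ind in enumerate(individuals):
        rows.append(
            dict(
                individual_id=i,
                age_y=ind.demographics.age,
                weight_kg=ind.demographics.weight,
                height_cm=ind.demographics.height,
                sex=ind.demographics.sex,
                renal_class=ind.renal_class.label,
                bsa_m2=ind.physiology.bsa,
                gfr_abs_ml_min=ind.physiology.gfr_absolute,
                kidney_volume_l=ind.physiology.kidney_volume,
                ts_scale=ind.physiology.ts_scale,
            )
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def timeseries_to_csv(series, path: str | Path, individual_id: int = 0) -> pd.DataFrame:
    df = pd.DataFrame(
        {"time_h": series.times, "conc_ug_per_ml": series.conc, "individual_id": individual_id}
    )
    df.to_csv(path, index=False)
    return df
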