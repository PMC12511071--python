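"""Model-qualification metrics: fold errors and goodness-of-fit fractions.

Two metrics drive model acceptance:

* MFE — the per-pair prediction ratio predicted/observed. The aggregate
  "mean MFE" is the arithmetic mean of the raw per-pair ratios.
* GMFE — geometric mean fold error, ``10^(mean |log10(pred/obs)|)``.
  The absolute value matters: it measures the typical fold distance from
  the identity line regardless of direction, so GMFE >= 1 always. It is
  computed from raw predicted/observed values, never from rounded
  per-pair MFEs.

A model is conventionally accepted when all PK-parameter MFE and GMFE
values stay below 2-fold. ``fold_fraction`` gives the share of pairs
within a k-fold band (k = 1.25, 1.5, 2 in the goodness-of-fit plots).

The module also ships the packaged reference table of predicted/observed
PK parameters (AUC0-inf, Cmax, tmax) for the adult development, adult
evaluation, RI-adult and pediatric cohorts, used as the fixed comparison
surface for the re-implemented engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PredObsPair",
    "ValidationSummary",
    "mfe",
    "mfe_mean",
    "gmfe",
    "gmfe_signed",
    "fold_fraction",
    "load_reference_table",
    "pairs_from_table",
    "summarize",
    "validate_engine",
    "FOLD_FACTORS",
]

FOLD_FACTORS = (1.25, 1.5, 2.0)

PARAMETERS = ("auc_0_inf", "cmax", "tmax")
COHORTS = ("adult_dev", "adult_eval", "ri_adult", "pediatric")


@dataclass(frozen=True)
class PredObsPair:
    parameter: str  # auc_0_inf | cmax | tmax
    predicted: float
    observed: float
    study_label: str = ""
    cohort: str = ""

    def __post_init__(self) -> None:
        if self.parameter not in PARAMETERS:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.predicted <= 0 or self.observed <= 0:
            raise ValueError("predicted and observed must be > 0")


@dataclass
class ValidationSummary:
    mfe_per_pair: List[float]
    mfe_mean: float
    gmfe: float
    fold_fractions: Dict[float, float]
    pass_2fold: bool
    n: int
    gaps: List[str] = field(default_factory=list)


def mfe(predicted: float, observed: float) -> float:
    """Per-pair fold error predicted/observed."""
    if predicted <= 0 or observed <= 0:
        raise ValueError("predicted and observed must be > 0")
    return predicted / observed


def mfe_mean(pairs: Sequence[PredObsPair]) -> float:
    """Arithmetic mean of the raw per-pair ratios."""
    if not pairs:
        raise ValueError("empty pair list")
    return float(np.mean([mfe(p.predicted, p.observed) for p in pairs]))


def gmfe(pairs: Sequence[PredObsPair]) -> float:
    """Geometric mean fold error, 10^(mean |log10(pred/obs)|); always >= 1."""
    if not pairs:
        raise ValueError("empty pair list")
    logs = [abs(math.log10(mfe(p.predicted, p.observed))) for p in pairs]
    return 10.0 ** float(np.mean(logs))


def gmfe_signed(pairs: Sequence[PredObsPair]) -> float:
    """Signed-log variant (geometric mean ratio); diagnostic only.

    Under- and over-predictions cancel here, so this is *not* the
    qualification metric — it exists to demonstrate that only the
    absolute-log form reproduces the reported cohort GMFEs.
    """
    if not pairs:
        raise ValueError("empty pair list")
    logs = [math.log10(mfe(p.predicted, p.observed)) for p in pairs]
    return 10.0 ** float(np.mean(logs))


def fold_fraction(pairs: Sequence[PredObsPair], factor: float) -> float:
    """Fraction of pairs with max(p/o, o/p) <= factor."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if not pairs:
        raise ValueError("empty pair list")
    within = sum(
        1 for p in pairs if max(p.predicted / p.observed, p.observed / p.predicted) <= factor
    )
    return within / len(pairs)


def load_reference_table() -> pd.DataFrame:
    """Packaged predicted/observed PK-parameter reference table."""
    with resources.files("gabapbpk.data").joinpath("pk_reference.csv").open() as fh:
        return pd.read_csv(fh)


def pairs_from_table(
    table: Optional[pd.DataFrame] = None,
    cohort: Optional[str] = None,
    parameter: Optional[str] = None,
) -> List[PredObsPair]:
    """PredObsPair list from (a slice of) the reference table."""
    if table is None:
        table = load_reference_table()
    if cohort is not None:
        table = table[table["cohort"] == cohort]
    if parameter is not None:
        table = table[table["parameter"] == parameter]
    return [
        PredObsPair(r.parameter, float(r.predicted), float(r.observed), r.study_label, r.cohort)
        for r in table.itertuples()
    ]


def summarize(pairs: Sequence[PredObsPair], gaps: Iterable[str] = ()) -> ValidationSummary:
    g = gmfe(pairs)
    per_pair = [mfe(p.predicted, p.observed) for p in pairs]
    passed = g < 2.0 and all(abs(math.log10(r)) < math.log10(2.0) for r in per_pair)
    return ValidationSummary(
        mfe_per_pair=per_pair,
        mfe_mean=float(np.mean(per_pair)),
        gmfe=g,
        fold_fractions={f: fold_fraction(pairs, f) for f in FOLD_FACTORS},
        pass_2fold=passed,
        n=len(pairs),
        gaps=list(gaps),
    )


def validate_engine(
    engine_predictions: Dict[str, Dict[str, float]],
    cohort: str,
    table: Optional[pd.DataFrame] = None,
) -> Dict[str, ValidationSummary]:
    """Compare engine predictions with the observed values of a cohort.

    ``engine_predictions`` maps regimen label (as in the reference table's
    ``regimen`` column) to a dict of parameter values. Fixture regimens
    with no engine prediction are reported as gaps, never silently
    dropped.
    """
    if table is None:
        table = load_reference_table()
    sub = table[table["cohort"] == cohort]
    if sub.empty:
        raise ValueError(f"unknown cohort {cohort!r}")
    out: Dict[str, ValidationSummary] = {}
    for param in PARAMETERS:
        rows = sub[sub["parameter"] == param]
        pairs: List[PredObsPair] = []
        gaps: List[str] = []
        for r in rows.itertuples():
            pred = engine_predictions.get(r.regimen, {}).get(param)
            if pred is None or (isinstance(pred, float) and math.isnan(pred)):
                gaps.append(f"{r.regimen}/{r.study_label}")
                continue
            pairs.append(PredObsPair(param, float(pred), float(r.observed), r.study_label, cohort))
        if not pairs:
            raise ValueError(f"no engine predictions matched cohort {cohort!r} for {param}")
        out[param] = summarize(pairs, gaps)
    return out
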