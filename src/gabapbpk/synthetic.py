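"""Synthetic "observed" concentration data with known ground truth.

Clinical mean concentration-time curves are emulated by closed-form
compartmental models (one- or two-compartment, first-order oral
absorption) with multiplicative log-normal residual error and optional
log-normal inter-individual variability on the PK parameters. Because the
generating truth is retained, NCA and the fold-error qualification
metrics can be tested for parameter recovery without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .engine import ConcTimeSeries, Regimen
from .nca import PKParams
from .validation import PredObsPair

__all__ = [
    "SyntheticStudySpec",
    "DEFAULT_SAMPLING_TIMES",
    "one_compartment_oral",
    "two_compartment_oral",
    "generate_profiles",
    "make_predobs_table",
]

#: Clinical-style sampling grid: dense around the expected absorption peak,
#: sparse over the elimination tail (h).
DEFAULT_SAMPLING_TIMES = (
    0.25, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 6.0, 8.0, 12.0, 16.0, 24.0, 36.0, 48.0
)


@dataclass
class SyntheticStudySpec:
    """Specification of a synthetic PK study.

    ``truth_params`` keys: CL (L/h), V (L) for the one-compartment model or
    V1, V2, Q (L, L, L/h) for the two-compartment model, ka (1/h), F.
    ``noise_cv`` is the multiplicative residual CV; ``iiv_cv`` maps
    parameter names to log-normal inter-individual CVs.
    """

    truth_model: str = "one_compartment_oral"
    truth_params: Dict[str, float] = field(
        default_factory=lambda: {"CL": 13.44, "V": 56.0, "ka": 0.45, "F": 1.0}
    )
    regimen: Optional[Regimen] = None
    sampling_times: Sequence[float] = DEFAULT_SAMPLING_TIMES
    noise_cv: float = 0.0
    n_subjects: int = 1
    iiv_cv: Dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.truth_model not in ("one_compartment_oral", "two_compartment_oral"):
            raise ValueError(f"unknown truth model {self.truth_model!r}")
        if any(v <= 0 for v in self.truth_params.values()):
            raise ValueError("truth parameters must be positive")
        if self.noise_cv < 0 or any(v < 0 for v in self.iiv_cv.values()):
            raise ValueError("noise_cv and iiv_cv must be >= 0")
        if self.regimen is None:
            self.regimen = Regimen.single(400.0, float(max(self.sampling_times)))


def one_compartment_oral(t: np.ndarray, dose: float, cl: float, v: float,
                         ka: float, f: float = 1.0) -> np.ndarray:
    """C(t) in ug/mL (= mg/L) after a single oral dose at t=0."""
    t = np.asarray(t, float)
    ke = cl / v
    if abs(ka - ke) < 1e-10:
        c = f * dose / v * ka * t * np.exp(-ka * t)
    else:
        c = f * dose * ka / (v * (ka - ke)) * (np.exp(-ke * t) - np.exp(-ka * t))
    return np.where(t >= 0, c, 0.0)


def two_compartment_oral(t: np.ndarray, dose: float, cl: float, v1: float,
                         v2: float, q: float, ka: float, f: float = 1.0) -> np.ndarray:
    """Central-compartment C(t) for the two-compartment oral model."""
    t = np.asarray(t, float)
    k10 = cl / v1
    k12 = q / v1
    k21 = q / v2
    s = k10 + k12 + k21
    disc = math.sqrt(s * s - 4.0 * k10 * k21)
    alpha = (s + disc) / 2.0
    beta = (s - disc) / 2.0
    coef = f * dose * ka / v1
    ca = (k21 - alpha) / ((ka - alpha) * (beta - alpha))
    cb = (k21 - beta) / ((ka - beta) * (alpha - beta))
    cc = (k21 - ka) / ((alpha - ka) * (beta - ka))
    c = coef * (ca * np.exp(-alpha * t) + cb * np.exp(-beta * t) + cc * np.exp(-ka * t))
    return np.where(t >= 0, c, 0.0)


def _truth_curve(spec: SyntheticStudySpec, params: Dict[str, float],
                 times: np.ndarray) -> np.ndarray:
    c = np.zeros_like(times, dtype=float)
    for event in spec.regimen.events:
        if event.amount == 0:
            continue
        tt = times - event.time
        if spec.truth_model == "one_compartment_oral":
            c += one_compartment_oral(tt, event.amount, params["CL"], params["V"],
                                      params["ka"], params.get("F", 1.0))
        else:
            c += two_compartment_oral(tt, event.amount, params["CL"], params["V1"],
                                      params["V2"], params["Q"], params["ka"],
                                      params.get("F", 1.0))
    return c


def generate_profiles(spec: SyntheticStudySpec) -> Tuple[List[ConcTimeSeries], Dict]:
    """Noisy subject profiles plus the retained truth record.

    Residual error is multiplicative log-normal: C_obs = C_true * exp(eps),
    eps ~ N(0, log(1 + noise_cv^2)), independent per sampling time.
    Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    times = np.asarray(sorted(spec.sampling_times), float)
    sigma2 = math.log(1.0 + spec.noise_cv**2)
    profiles: List[ConcTimeSeries] = []
    subjects = []
    for i in range(spec.n_subjects):
        params = dict(spec.truth_params)
        for name, cv in spec.iiv_cv.items():
            if cv > 0 and name in params:
                s2 = math.log(1.0 + cv**2)
                params[name] *= float(rng.lognormal(-s2 / 2.0, math.sqrt(s2)))
        c = _truth_curve(spec, params, times)
        if spec.noise_cv > 0:
            c = c * np.exp(rng.normal(0.0, math.sqrt(sigma2), size=times.size))
        profiles.append(
            ConcTimeSeries(times, c, meta={"subject": i, "truth_params": params})
        )
        subjects.append(params)
    truth = {
        "model": spec.truth_model,
        "population_params": dict(spec.truth_params),
        "subject_params": subjects,
        "noise_cv": spec.noise_cv,
        "seed": spec.seed,
    }
    return profiles, truth


def make_predobs_table(
    predicted: Dict[str, PKParams],
    observed: Dict[str, PKParams],
    parameters: Sequence[str] = ("auc_0_inf", "cmax", "tmax"),
    cohort: str = "synthetic",
) -> List[PredObsPair]:
    """Pair engine-predicted with synthetic-observed PK parameters.

    Keys of the two dicts are regimen/study labels and must match exactly;
    a mismatch is an error, never a silent drop.
    """
    if set(predicted) != set(observed):
        missing = set(predicted) ^ set(observed)
        raise ValueError(f"regimen mismatch between predicted and observed: {sorted(missing)}")
    pairs: List[PredObsPair] = []
    for label in sorted(predicted):
        for param in parameters:
            p = getattr(predicted[label], param)
            o = getattr(observed[label], param)
            pairs.append(PredObsPair(param, float(p), float(o), label, cohort))
    return pairs
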