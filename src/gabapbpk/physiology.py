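"""Virtual individuals and populations for the gabapentin PBPK analyses.

Builds representative adults, pediatric age bands, and renal-impairment (RI)
classes with age-scaled physiology: organ volumes and blood flows, body
surface area, absolute glomerular filtration rate (GFR), kidney volume and
the tubular-secretion scale used by the renal clearance model.

Conventions
-----------
* GFR is specified normalized to 1.73 m2 body surface area (mL/min/1.73 m2)
  and converted per individual via BSA and an age maturation function.
* Renal function classes carry representative normalized GFR values of
  100 (normal), 30 (mild), 15 (moderate) and 5 (severe) mL/min/1.73 m2.
* Kidney volume and the specific tubular-secretion scale are reduced with
  RI severity; the reduction factors are calibrated constants (see
  :mod:`gabapbpk.calibration`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

__all__ = [
    "Demographics",
    "RenalFunctionClass",
    "PhysiologyState",
    "VirtualIndividual",
    "RENAL_CLASSES",
    "ADULT_REFERENCE",
    "ORGAN_REFERENCE",
    "AGE_BANDS",
    "REPRESENTATIVE_DEMOGRAPHICS",
    "bsa",
    "gfr_maturation",
    "build_individual",
    "sample_population",
    "representative_individual",
    "typical_weight_height",
]

MIN_AGE_YEARS = 1.0 / 12.0  # youngest simulated group starts at 1 month


@dataclass(frozen=True)
class Demographics:
    """Demographic description of a (virtual) subject."""

    age: float  # years
    weight: float  # kg
    height: float  # cm
    sex: str = "male"
    ethnicity: str = "unspecified"

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"age must be >= 0, got {self.age}")
        if self.weight <= 0:
            raise ValueError(f"weight must be > 0, got {self.weight}")
        if self.height <= 0:
            raise ValueError(f"height must be > 0, got {self.height}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")


@dataclass(frozen=True)
class RenalFunctionClass:
    """Renal function category with its representative normalized GFR."""

    label: str
    representative_gfr_normalized: float  # mL/min/1.73 m2
    gfr_range: Tuple[float, Optional[float]]  # class bounds, mL/min/1.73 m2


#: FDA-style renal function classes. Bounds: normal >=60, mild 30-59,
#: moderate 15-29, severe <15 mL/min/1.73 m2.
RENAL_CLASSES: Dict[str, RenalFunctionClass] = {
    "normal": RenalFunctionClass("normal", 100.0, (60.0, None)),
    "mild": RenalFunctionClass("mild", 30.0, (30.0, 59.0)),
    "moderate": RenalFunctionClass("moderate", 15.0, (15.0, 29.0)),
    "severe": RenalFunctionClass("severe", 5.0, (0.0, 15.0)),
}

#: Reference adult used throughout calibration (weight kg, height cm).
ADULT_REFERENCE = Demographics(age=30.0, weight=70.0, height=170.0)

#: Reference adult organ volumes (L) and blood flows (L/h), ICRP-style.
#: The liver flow is the hepatic-artery flow; the portal (gut) outflow is
#: added to it inside the ODE model. "rest" lumps bone, heart, lung tissue
#: and remaining carcass. Kidney volume is a calibrated effective volume
#: (see gabapbpk.calibration) and is inserted at import time below.
ORGAN_REFERENCE: Dict[str, Tuple[float, float]] = {
    "gut": (1.2, 45.0),
    "liver": (1.8, 18.0),
    "kidney": (0.273, 66.0),  # volume replaced by calibrated value below
    "muscle": (29.0, 45.0),
    "adipose": (13.5, 19.0),
    "skin": (3.3, 19.0),
    "brain": (1.4, 46.0),
    "rest": (12.0, 60.0),
}

BLOOD_REFERENCE = {"arterial": 1.7, "venous": 3.5}  # L
HEMATOCRIT = 0.45

AGE_BANDS = ("1m-3y", "3-12y", "12-17y", "adult")

#: Representative (median) individual per age band: (age y, weight kg, height cm).
REPRESENTATIVE_DEMOGRAPHICS: Dict[str, Tuple[float, float, float]] = {
    "1m-3y": (1.5, 11.25, 81.0),
    "3-12y": (8.0, 26.0, 128.0),
    "12-17y": (14.0, 50.0, 160.0),
    "adult": (30.0, 70.0, 170.0),
}

# Age-typical median body size (growth-chart style anchors, linearly
# interpolated; constant above 18 y).
_GROWTH_AGE = np.array([0.0, 0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 5.0, 8.0, 10.0, 12.0, 14.0, 16.0, 18.0])
_GROWTH_WT = np.array([3.5, 6.0, 7.5, 10.0, 11.25, 12.5, 14.5, 18.5, 26.0, 32.0, 40.0, 50.0, 60.0, 70.0])
_GROWTH_HT = np.array([50.0, 60.0, 66.0, 75.0, 81.0, 87.0, 95.0, 109.0, 128.0, 138.0, 149.0, 160.0, 170.0, 170.0])


@dataclass
class PhysiologyState:
    """Derived physiological state of a virtual individual."""

    organs: Dict[str, Tuple[float, float]]  # name -> (volume L, blood flow L/h)
    blood_volumes: Dict[str, float]  # arterial / venous, L
    gfr_absolute: float  # mL/min
    kidney_volume: float  # L
    hematocrit: float
    bsa: float  # m2
    ts_scale: float  # multiplier on the specific tubular secretion rate

    @property
    def cardiac_output(self) -> float:
        """Total blood flow through the system, L/h."""
        return sum(q for _, q in self.organs.values())

    def total_volume(self) -> float:
        return sum(v for v, _ in self.organs.values()) + sum(self.blood_volumes.values())


@dataclass
class VirtualIndividual:
    demographics: Demographics
    renal_class: RenalFunctionClass
    physiology: PhysiologyState


def bsa(demographics: Demographics) -> float:
    """Body surface area (m2) by the Du Bois formula.

    BSA = 0.007184 * W^0.425 * H^0.725 with W in kg, H in cm.
    """
    return 0.007184 * demographics.weight**0.425 * demographics.height**0.725


def gfr_maturation(age: float) -> float:
    """Fraction of the adult normalized GFR attained at a given age.

    A Hill-type function of postnatal age anchored at ~0.30 at birth and
    >=0.95 by age 2, reflecting the rapid postnatal maturation of
    glomerular filtration; returns exactly 1.0 from age 18 on.
    """
    if age < 0:
        raise ValueError(f"age must be >= 0, got {age}")
    if age >= 18.0:
        return 1.0
    a50, hill = 0.5, 2.0
    return 0.3 + 0.7 * age**hill / (age**hill + a50**hill)


def typical_weight_height(age: float) -> Tuple[float, float]:
    """Age-typical median weight (kg) and height (cm)."""
    w = float(np.interp(age, _GROWTH_AGE, _GROWTH_WT))
    h = float(np.interp(age, _GROWTH_AGE, _GROWTH_HT))
    return w, h


def _ri_scaling(label: str, pediatric: bool) -> Tuple[float, float]:
    """(kidney volume multiplier, tubular secretion scale) for an RI class.

    The values are calibrated constants; imported lazily to avoid a module
    cycle with gabapbpk.calibration.
    """
    from . import calibration

    kmult = calibration.KIDNEY_VOLUME_MULTIPLIER[label]
    if pediatric:
        ts = calibration.TS_SCALE_PEDIATRIC[label]
    else:
        ts = calibration.TS_SCALE_ADULT[label]
    return kmult, ts


def build_individual(
    demographics: Demographics,
    renal_class: RenalFunctionClass | str = "normal",
) -> VirtualIndividual:
    """Construct a virtual individual with scaled physiology.

    Organ volumes scale proportionally to body weight; blood flows scale
    with weight^0.75 (allometric cardiac-output scaling). Absolute GFR is
    representative_gfr_normalized * BSA/1.73 * maturation(age). For RI
    classes the kidney volume and tubular-secretion scale are reduced by
    calibrated class factors; pediatric individuals (< 18 y) use the
    pediatric secretion scales.
    """
    if isinstance(renal_class, str):
        try:
            renal_class = RENAL_CLASSES[renal_class]
        except KeyError:
            raise ValueError(f"unknown renal class {renal_class!r}") from None
    elif renal_class.label not in RENAL_CLASSES:
        raise ValueError(f"unknown renal class {renal_class.label!r}")

    if demographics.age < MIN_AGE_YEARS:
        raise ValueError(
            f"age {demographics.age:.3f} y below supported minimum of 1 month"
        )

    from . import calibration

    wfrac = demographics.weight / ADULT_REFERENCE.weight
    qfrac = wfrac**0.75
    pediatric = demographics.age < 18.0
    kmult, ts_scale = _ri_scaling(renal_class.label, pediatric)

    organs: Dict[str, Tuple[float, float]] = {}
    for name, (v_ref, q_ref) in ORGAN_REFERENCE.items():
        v = v_ref * wfrac
        if name == "kidney":
            v = calibration.KIDNEY_VOLUME_REF_L * wfrac * kmult
        organs[name] = (v, q_ref * qfrac)

    surface = bsa(demographics)
    gfr_abs = (
        renal_class.representative_gfr_normalized
        * surface
        / 1.73
        * gfr_maturation(demographics.age)
    )
    phys = PhysiologyState(
        organs=organs,
        blood_volumes={k: v * wfrac for k, v in BLOOD_REFERENCE.items()},
        gfr_absolute=gfr_abs,
        kidney_volume=organs["kidney"][0],
        hematocrit=HEMATOCRIT,
        bsa=surface,
        ts_scale=ts_scale,
    )
    return VirtualIndividual(demographics, renal_class, phys)


def representative_individual(
    age_band: str, renal_class: RenalFunctionClass | str = "normal"
) -> VirtualIndividual:
    """Median individual of an age band (used for all validation targets)."""
    try:
        age, weight, height = REPRESENTATIVE_DEMOGRAPHICS[age_band]
    except KeyError:
        raise ValueError(f"unknown age band {age_band!r}") from None
    return build_individual(Demographics(age, weight, height), renal_class)


def sample_population(
    n: int,
    age_range: Tuple[float, float],
    renal_class: RenalFunctionClass | str = "normal",
    seed: int = 0,
    weight_cv: float = 0.15,
    height_cv: float = 0.04,
) -> List[VirtualIndividual]:
    """Monte Carlo population with log-normal size variability.

    Ages are sampled uniformly on ``[age_range[0], age_range[1])``; weight
    and height are log-normal around the age-typical medians with the given
    coefficients of variation. Bit-reproducible for a fixed seed.
    """
    lo, hi = age_range
    if not (MIN_AGE_YEARS <= lo < hi):
        raise ValueError(f"invalid age range {age_range}")
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    out: List[VirtualIndividual] = []
    for _ in range(n):
        age = float(rng.uniform(lo, hi))
        w_med, h_med = typical_weight_height(age)
        w = w_med * float(rng.lognormal(0.0, np.sqrt(np.log(1 + weight_cv**2))))
        h = h_med * float(rng.lognormal(0.0, np.sqrt(np.log(1 + height_cv**2))))
        sex = "male" if rng.random() < 0.5 else "female"
        out.append(build_individual(Demographics(age, w, h, sex=sex), renal_class))
    return out
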