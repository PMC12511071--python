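"""Reduced whole-body PBPK engine for gabapentin.

An 11-compartment perfusion-limited model: a gut-lumen absorption depot,
eight perfused tissues (gut, liver, kidney, muscle, adipose, skin, brain,
rest-of-body) and arterial/venous blood pools. Oral drug is released into
the lumen (bolus or zero-order), absorbed first-order with rate ``ka``;
the absorbed fraction ``fabs`` enters the gut tissue and reaches the liver
via the portal flow. There is no metabolic clearance: elimination is
renal only,

    CL_renal = fup * GFR_fraction * GFR_abs  +  fup * TSspec * ts_scale * V_kidney,

an unbound filtration term plus a first-order specific tubular secretion
term scaled by kidney volume (capped at kidney plasma flow). The renal
elimination rate is driven by the arterial plasma concentration (filtration
acts on afferent plasma) and drawn from the kidney compartment, which makes
the model's venous-plasma AUC0-inf equal fabs*Dose/CL exactly — the
property the calibration chain relies on.

Internal unit canon: amounts in umol, volumes in L, times in h. Doses are
given in mg and converted via the molecular weight; reported plasma
concentrations are ug/mL (venous).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from . import calibration, partition
from .physiology import VirtualIndividual

__all__ = [
    "DrugParams",
    "GABAPENTIN",
    "DoseEvent",
    "Regimen",
    "ConcTimeSeries",
    "REGIMEN_INTERVALS",
    "partition_coefficients",
    "renal_clearance",
    "build_ode",
    "apply_release",
    "simulate",
    "SolverError",
]

ORGAN_ORDER = ("gut", "liver", "kidney", "muscle", "adipose", "skin", "brain", "rest")

REGIMEN_INTERVALS = {"qd": 24.0, "bid": 12.0, "tid": 8.0, "qod": 48.0}


class SolverError(RuntimeError):
    """ODE integration failure, with scenario context."""


@dataclass(frozen=True)
class DrugParams:
    """Physicochemical and ADME parameters of the simulated compound."""

    logp: float
    pka_acid: float
    pka_base: float
    mw: float  # g/mol
    solubility_ph7: float  # mg/mL (informational; no dissolution model)
    fup: float  # fraction unbound in plasma
    b2p: float  # blood-to-plasma concentration ratio
    gfr_fraction: float  # fraction of GFR available for filtration
    ts_spec: float  # specific tubular secretion rate, 1/min
    cl_renal_ref: float  # identified total renal clearance, mL/min/kg
    ka: float  # first-order absorption rate, 1/h
    fabs: float  # fraction of released drug absorbed
    kp_scale: float  # global scalar on composition-based Kp
    kp_set: Optional[Dict[str, float]] = None  # explicit per-organ override

    def __post_init__(self) -> None:
        if not (0.0 < self.fup <= 1.0):
            raise ValueError("fup must be in (0, 1]")
        if not (0.0 <= self.gfr_fraction <= 1.0):
            raise ValueError("gfr_fraction must be in [0, 1]")
        if self.ts_spec < 0:
            raise ValueError("ts_spec must be >= 0")
        if self.ka <= 0:
            raise ValueError("ka must be > 0")
        if not (0.0 < self.fabs <= 1.0):
            raise ValueError("fabs must be in (0, 1]")
        if self.kp_set is not None and any(v <= 0 for v in self.kp_set.values()):
            raise ValueError("all partition coefficients must be > 0")


#: Operative gabapentin parameter set (drug parameter table values plus the
#: calibrated absorption/distribution constants).
GABAPENTIN = DrugParams(
    logp=calibration.LOGP,
    pka_acid=calibration.PKA_ACID,
    pka_base=calibration.PKA_BASE,
    mw=171.2368,
    solubility_ph7=50.0,
    fup=calibration.FUP,
    b2p=calibration.B2P,
    gfr_fraction=calibration.GFR_FRACTION,
    ts_spec=calibration.TS_SPEC_PER_MIN,
    cl_renal_ref=calibration.CL_RENAL_REF_ML_MIN_KG,
    ka=calibration.KA_PER_H,
    fabs=calibration.FABS,
    kp_scale=calibration.KP_SCALE,
)


@dataclass(frozen=True)
class DoseEvent:
    """A single oral dose. ``release`` is 'immediate' or 'zero_order'."""

    time: float  # h
    amount: float  # mg
    release: str = "immediate"
    duration: float = 0.0  # h, zero-order release duration

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("dose time must be >= 0")
        if self.amount < 0:
            raise ValueError("dose amount must be >= 0")
        if self.release not in ("immediate", "zero_order"):
            raise ValueError(f"unknown release {self.release!r}")
        if self.release == "zero_order" and self.duration <= 0:
            raise ValueError("zero_order release requires duration > 0")


@dataclass(frozen=True)
class Regimen:
    """Ordered dosing schedule over a simulation duration."""

    events: Tuple[DoseEvent, ...]
    duration: float  # h
    label: str = "custom"

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("dose events must be sorted by time")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")

    @classmethod
    def single(cls, amount_mg: float, duration: float = 48.0, release: str = "immediate",
               release_duration: float = 0.0) -> "Regimen":
        return cls((DoseEvent(0.0, amount_mg, release, release_duration),), duration, "single")

    @classmethod
    def repeated(cls, label: str, amount_mg: float, days: float,
                 release: str = "immediate", release_duration: float = 0.0,
                 extra_duration: float = 0.0) -> "Regimen":
        """qd / bid / tid / qod schedule of equal doses over ``days`` days."""
        try:
            interval = REGIMEN_INTERVALS[label]
        except KeyError:
            raise ValueError(f"unknown regimen label {label!r}") from None
        total = days * 24.0
        times = np.arange(0.0, total - 1e-9, interval)
        events = tuple(DoseEvent(float(t), amount_mg, release, release_duration) for t in times)
        return cls(events, total + extra_duration, label)

    def total_dose(self) -> float:
        return sum(e.amount for e in self.events)

    def scaled(self, factor: float) -> "Regimen":
        events = tuple(replace(e, amount=e.amount * factor) for e in self.events)
        return Regimen(events, self.duration, self.label)


@dataclass
class ConcTimeSeries:
    """Venous plasma concentration (ug/mL) on a strictly increasing grid (h)."""

    times: np.ndarray
    conc: np.ndarray
    individual: Optional[VirtualIndividual] = None
    regimen: Optional[Regimen] = None
    meta: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.times.shape != self.conc.shape:
            raise ValueError("times and conc must align")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


def partition_coefficients(drug: DrugParams) -> Dict[str, float]:
    """Per-organ tissue:plasma partition coefficients.

    Composition-based raw values (tissue water + neutral lipid against
    plasma, at the zwitterion-corrected logD) multiplied by the drug's
    global ``kp_scale``. Dose-independent by construction.
    """
    if drug.kp_set is not None:
        return dict(drug.kp_set)
    logd = partition.log_d(drug.logp, drug.pka_acid, drug.pka_base)
    return {organ: drug.kp_scale * partition.kp_raw(organ, logd) for organ in ORGAN_ORDER}


def renal_clearance(drug: DrugParams, phys) -> float:
    """Total renal plasma clearance, L/h.

    fup*GFR filtration plus fup-driven first-order specific tubular
    secretion scaled by kidney volume and the RI secretion scale; capped at
    kidney plasma flow for physical realizability. Strictly decreasing in
    RI severity by construction of the class scalings.
    """
    filtration = drug.fup * drug.gfr_fraction * phys.gfr_absolute * 0.06  # mL/min -> L/h
    secretion = drug.fup * drug.ts_spec * 60.0 * phys.ts_scale * phys.kidney_volume
    cl = filtration + secretion
    kidney_plasma_flow = phys.organs["kidney"][1] * (1.0 - phys.hematocrit)
    return min(cl, kidney_plasma_flow)


def apply_release(event: DoseEvent, mw: float) -> Tuple[float, Callable[[float], float]]:
    """Input-rate representation of a dose event.

    Returns ``(bolus_umol, rate_fn)``: an instantaneous lumen amount added
    at the event time (immediate release) and a rate function (umol/h) of
    absolute time for zero-order release.
    """
    amount_umol = event.amount / mw * 1000.0  # mg -> umol
    if event.release == "immediate":
        return amount_umol, lambda t: 0.0
    rate = amount_umol / event.duration
    t0, t1 = event.time, event.time + event.duration

    def rate_fn(t: float, _r=rate, _t0=t0, _t1=t1) -> float:
        return _r if _t0 <= t < _t1 else 0.0

    return 0.0, rate_fn


# State vector layout:
#   0: gut lumen (umol)        1..8: tissues in ORGAN_ORDER (umol)
#   9: arterial blood  10: venous blood
#   11: cumulative renally eliminated   12: cumulative unabsorbed
N_STATES = 13
IDX_LUMEN, IDX_ART, IDX_VEN, IDX_ELIM, IDX_UNABS = 0, 9, 10, 11, 12
PLASMA_INDEX = IDX_VEN  # reported concentration is venous plasma


def build_ode(individual: VirtualIndividual, drug: DrugParams):
    """Right-hand side of the mass-balanced PBPK system.

    Returns ``(rhs, info)`` where ``rhs(t, y, release_rate_fn)`` gives
    dy/dt in umol/h and ``info`` carries volumes/flows/Kp/CL for reuse.
    """
    phys = individual.physiology
    missing = [o for o in ORGAN_ORDER if o not in phys.organs]
    if missing:
        raise ValueError(f"physiology missing organs: {missing}")

    kp = partition_coefficients(drug)
    if set(kp) != set(ORGAN_ORDER):
        raise ValueError("partition coefficient set inconsistent with organ set")

    vols = np.array([phys.organs[o][0] for o in ORGAN_ORDER])
    flows = np.array([phys.organs[o][1] for o in ORGAN_ORDER])
    kps = np.array([kp[o] for o in ORGAN_ORDER])
    v_art = phys.blood_volumes["arterial"]
    v_ven = phys.blood_volumes["venous"]
    bp = drug.b2p
    cl = renal_clearance(drug, phys)  # plasma L/h
    ka = drug.ka
    fabs = drug.fabs

    i_gut, i_liv, i_kid = 0, 1, 2
    q_gut, q_ha = flows[i_gut], flows[i_liv]
    q_liv_out = q_gut + q_ha
    co = float(flows.sum())  # total systemic flow (liver counted as q_ha + portal)

    def rhs(t: float, y: np.ndarray, release_rate: Callable[[float], float]) -> np.ndarray:
        dy = np.empty(N_STATES)
        a_lum = y[IDX_LUMEN]
        c_art_b = y[IDX_ART] / v_art
        c_ven_b = y[IDX_VEN] / v_ven
        c_t = y[1:9] / vols
        c_out = c_t * bp / kps  # emergent venous blood conc per organ

        absorbed = ka * a_lum
        dy[IDX_LUMEN] = release_rate(t) - absorbed
        dy[IDX_UNABS] = (1.0 - fabs) * absorbed

        # tissue balances (perfusion-limited)
        dy[1:9] = flows * (c_art_b - c_out)
        # gut receives the absorbed fraction
        dy[1 + i_gut] += fabs * absorbed
        # liver: hepatic artery + portal inflow, common outflow
        dy[1 + i_liv] = q_ha * c_art_b + q_gut * c_out[i_gut] - q_liv_out * c_out[i_liv]
        # kidney: renal elimination driven by arterial plasma concentration
        elim = cl * c_art_b / bp
        dy[1 + i_kid] -= elim
        dy[IDX_ELIM] = elim

        venous_in = float(np.dot(flows[2:], c_out[2:])) + q_liv_out * c_out[i_liv]
        dy[IDX_VEN] = venous_in - co * c_ven_b
        dy[IDX_ART] = co * (c_ven_b - c_art_b)
        return dy

    info = {
        "volumes": vols,
        "flows": flows,
        "kp": kp,
        "clearance_l_h": cl,
        "cardiac_output": co,
        "v_art": v_art,
        "v_ven": v_ven,
    }
    return rhs, info


def _segment_breakpoints(regimen: Regimen) -> List[float]:
    pts = {0.0, regimen.duration}
    for e in regimen.events:
        pts.add(e.time)
        if e.release == "zero_order":
            pts.add(min(e.time + e.duration, regimen.duration))
    return sorted(p for p in pts if 0.0 <= p <= regimen.duration)


def simulate(
    individual: VirtualIndividual,
    drug: DrugParams,
    regimen: Regimen,
    grid: Optional[Sequence[float]] = None,
    dt: float = 0.05,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> ConcTimeSeries:
    """Simulate a dosing regimen and return the venous plasma profile.

    Dosing is implemented as integration restarts at event times (bolus
    doses step the lumen amount; zero-order release adds a constant lumen
    input rate). The output grid defaults to a fixed ``dt`` spacing.
    """
    if grid is None:
        grid = np.arange(0.0, regimen.duration + dt / 2, dt)
    grid = np.asarray(grid, dtype=float)
    if grid.size and grid[-1] > regimen.duration + 1e-9:
        raise ValueError("grid extends beyond regimen duration")
    for e in regimen.events:
        if e.time > regimen.duration:
            raise ValueError("dose event beyond regimen duration")

    rhs, info = build_ode(individual, drug)

    bolus_at: Dict[float, float] = {}
    rate_fns: List[Callable[[float], float]] = []
    for e in regimen.events:
        bolus, rate_fn = apply_release(e, drug.mw)
        if bolus:
            bolus_at[e.time] = bolus_at.get(e.time, 0.0) + bolus
        if e.release == "zero_order":
            rate_fns.append(rate_fn)

    def release_rate(t: float) -> float:
        return sum(f(t) for f in rate_fns) if rate_fns else 0.0

    def to_plasma(a_ven: np.ndarray) -> np.ndarray:
        return a_ven / info["v_ven"] / drug.b2p * drug.mw / 1000.0

    y = np.zeros(N_STATES)
    conc = np.full(grid.size, np.nan)
    breaks = _segment_breakpoints(regimen)
    last = breaks[-1]
    for t0, t1 in zip(breaks, breaks[1:]):
        if t0 in bolus_at:
            y[IDX_LUMEN] += bolus_at[t0]
        # half-open segment [t0, t1); the overall end point belongs to the
        # final segment
        if t1 >= last:
            seg_mask = (grid >= t0 - 1e-12) & (grid <= t1 + 1e-12)
        else:
            seg_mask = (grid >= t0 - 1e-12) & (grid < t1 - 1e-12)
        t_eval = np.clip(grid[seg_mask], t0, t1)
        sol = solve_ivp(
            rhs,
            (t0, t1),
            y,
            method="LSODA",
            t_eval=t_eval if t_eval.size else None,
            rtol=rtol,
            atol=atol,
            args=(release_rate,),
        )
        if not sol.success:
            raise SolverError(
                f"integration failed on [{t0}, {t1}] h for regimen "
                f"{regimen.label!r}: {sol.message}"
            )
        if t_eval.size:
            conc[seg_mask] = to_plasma(sol.y[IDX_VEN])
            y = sol.y[:, -1]
            if sol.t[-1] < t1 - 1e-9:
                sol2 = solve_ivp(rhs, (sol.t[-1], t1), y, method="LSODA",
                                 rtol=rtol, atol=atol, args=(release_rate,))
                if not sol2.success:
                    raise SolverError(f"integration failed near {t1} h: {sol2.message}")
                y = sol2.y[:, -1]
        else:
            y = sol.y[:, -1]

    if np.isnan(conc).any():
        raise SolverError("output grid not fully covered by dose segments")
    conc = np.clip(conc, 0.0, None)
    ts = ConcTimeSeries(
        times=grid,
        conc=conc,
        individual=individual,
        regimen=regimen,
        meta={
            "clearance_l_h": info["clearance_l_h"],
            "final_state_umol": y.copy(),
            "total_dose_mg": regimen.total_dose(),
            "solver": {"method": "LSODA", "rtol": rtol, "atol": atol, "dt": dt},
        },
    )
    return ts


def mass_balance_error(ts: ConcTimeSeries, drug: DrugParams) -> float:
    """|system + eliminated + unabsorbed - dosed| as a fraction of dose."""
    y = ts.meta["final_state_umol"]
    total_umol = float(np.sum(y[:IDX_ELIM + 1])) + float(y[IDX_UNABS])
    dosed_umol = ts.meta["total_dose_mg"] / drug.mw * 1000.0
    if dosed_umol == 0:
        return abs(total_umol)
    return abs(total_umol - dosed_umol) / dosed_umol


def vss_plasma(individual: VirtualIndividual, drug: DrugParams) -> float:
    """Plasma-referenced steady-state volume of distribution, L."""
    kp = partition_coefficients(drug)
    phys = individual.physiology
    v = sum(phys.organs[o][0] * kp[o] for o in ORGAN_ORDER)
    v += sum(phys.blood_volumes.values()) * drug.b2p
    return v
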