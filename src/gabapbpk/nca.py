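"""Non-compartmental analysis of concentration-time profiles.

Conventions (stated for reproducibility):

* AUC by linear-up / log-down trapezoid (log interpolation on strictly
  decreasing positive segments, linear otherwise).
* Terminal slope (lambda_z) from a log-linear regression over the trailing
  3-6 points after tmax, choosing the window with the best adjusted r^2;
  the fit is rejected (result flagged) if lambda_z <= 0 or r^2 < 0.8.
* AUC extrapolation to infinity as C_last / lambda_z.
* Steady-state exposure is reported per 24 h: for a 48 h (every-other-day)
  interval the interval AUC is halved so multi-regimen comparisons are
  like-for-like.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .engine import ConcTimeSeries

__all__ = ["PKParams", "nca_single_dose", "nca_steady_state", "auc_trapezoid"]


@dataclass
class PKParams:
    """Non-compartmental PK parameters.

    ``auc_0_inf`` is NaN when no credible terminal phase was identified
    (``flags`` then explains why).
    """

    auc_0_inf: float = math.nan  # ug*h/mL
    auc_0_24: float = math.nan  # ug*h/mL
    auc_0_t: float = math.nan  # ug*h/mL to the last time point
    cmax: float = math.nan  # ug/mL
    tmax: float = math.nan  # h
    lambda_z: float = math.nan  # 1/h
    lambda_z_r2: float = math.nan
    auc_extrap_fraction: float = math.nan
    flags: list = field(default_factory=list)

    @property
    def valid_terminal_phase(self) -> bool:
        return not math.isnan(self.auc_0_inf)


def auc_trapezoid(times: np.ndarray, conc: np.ndarray) -> float:
    """Linear-up/log-down trapezoidal AUC over the full span."""
    t = np.asarray(times, float)
    c = np.asarray(conc, float)
    dt = np.diff(t)
    c1, c2 = c[:-1], c[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ok = (c2 < c1) & (c2 > 0) & (c1 > 0)
        seg = np.where(
            log_ok,
            (c1 - c2) / np.log(np.where(log_ok, c1 / np.where(c2 > 0, c2, 1.0), 1.0)),
            0.5 * (c1 + c2),
        )
    return float(np.sum(seg * dt))


def _terminal_fit(times: np.ndarray, conc: np.ndarray, i_tmax: int):
    """Best adjusted-r^2 log-linear fit over trailing 3-6 points after tmax."""
    mask = np.arange(conc.size) > i_tmax
    mask &= conc > 0
    idx = np.nonzero(mask)[0]
    best = None
    for k in range(3, 7):
        if idx.size < k:
            break
        sel = idx[-k:]
        t, lc = times[sel], np.log(conc[sel])
        slope, intercept = np.polyfit(t, lc, 1)
        resid = lc - (slope * t + intercept)
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((lc - lc.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res < 1e-20 else 0.0)
        adj = 1.0 - (1.0 - r2) * (k - 1) / (k - 2)
        if best is None or adj > best[0]:
            best = (adj, r2, -slope)
    return best  # (adj_r2, r2, lambda_z) or None


def nca_single_dose(ts: ConcTimeSeries) -> PKParams:
    """Single-dose NCA: Cmax/tmax, AUC0-t, lambda_z and AUC0-inf."""
    t, c = ts.times, ts.conc
    if t.size < 4:
        raise ValueError("need at least 4 concentration points")
    out = PKParams()
    i_max = int(np.argmax(c))
    out.cmax = float(c[i_max])
    out.tmax = float(t[i_max])
    out.auc_0_t = auc_trapezoid(t, c)
    if t[-1] >= 24.0:
        m = t <= 24.0 + 1e-9
        out.auc_0_24 = auc_trapezoid(t[m], c[m])
    if out.cmax <= 0:
        out.flags.append("all-zero profile; terminal phase undefined")
        out.auc_0_t = 0.0
        out.auc_0_24 = 0.0 if t[-1] >= 24.0 else math.nan
        return out
    if i_max >= t.size - 3:
        out.flags.append("no terminal phase: concentration still rising")
        return out
    fit = _terminal_fit(t, c, i_max)
    if fit is None:
        out.flags.append("insufficient points after tmax for terminal fit")
        return out
    _adj, r2, lam = fit
    if lam <= 0 or r2 < 0.8:
        out.flags.append(f"terminal fit rejected (lambda_z={lam:.3g}, r2={r2:.3f})")
        out.lambda_z = lam
        out.lambda_z_r2 = r2
        return out
    out.lambda_z = lam
    out.lambda_z_r2 = r2
    c_last = float(c[c > 0][-1])
    extrap = c_last / lam
    out.auc_0_inf = out.auc_0_t + extrap
    out.auc_extrap_fraction = extrap / out.auc_0_inf
    return out


def nca_steady_state(ts: ConcTimeSeries, interval: float) -> PKParams:
    """Exposure metrics over the final dosing window at steady state.

    Reports AUC normalized per 24 h: for ``interval`` = 48 h the final
    48 h AUC is halved; otherwise the AUC over the final 24 h window is
    used directly. Cmax/tmax are taken within the window, tmax relative to
    the window start.
    """
    t, c = ts.times, ts.conc
    if interval <= 0:
        raise ValueError("interval must be > 0")
    if t[-1] < 3 * interval:
        raise ValueError("simulation must cover at least 3 dosing intervals")
    window = 48.0 if interval == 48.0 else 24.0
    if t[-1] < window:
        raise ValueError("window exceeds simulated span")
    t0 = t[-1] - window
    m = t >= t0 - 1e-9
    tw, cw = t[m], c[m]
    out = PKParams()
    auc_w = auc_trapezoid(tw, cw)
    out.auc_0_24 = auc_w / 2.0 if window == 48.0 else auc_w
    i_max = int(np.argmax(cw))
    out.cmax = float(cw[i_max])
    out.tmax = float(tw[i_max] - tw[0])
    if window == 48.0:
        out.flags.append("qod interval: 48 h AUC halved to per-24 h")
    return out
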