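"""Tissue:plasma partition primitives for the simplified distribution model.

Gabapentin is a small zwitterion (acidic pKa 4.63, basic pKa 9.91): at
plasma pH almost none of it is neutral, so its effective lipid partitioning
is tiny and tissue distribution is essentially water-driven. Each organ's
raw partition coefficient is a water + neutral-lipid composition ratio
against plasma; a single global scalar (calibrated to the steady-state
volume of distribution, see :mod:`gabapbpk.calibration`) absorbs the
remaining unmodeled binding.
"""

from __future__ import annotations

import math
from typing import Dict

#: Fractional tissue composition (water, neutral lipid); standard
#: composition-table values. "rest" lumps bone and remaining carcass.
TISSUE_COMPOSITION: Dict[str, tuple] = {
    "gut": (0.718, 0.0487),
    "liver": (0.751, 0.0348),
    "kidney": (0.783, 0.0207),
    "muscle": (0.760, 0.0238),
    "adipose": (0.180, 0.790),
    "skin": (0.718, 0.0284),
    "brain": (0.770, 0.0510),
    "rest": (0.400, 0.0200),
}

PLASMA_COMPOSITION = (0.945, 0.0035)


def log_d(logp: float, pka_acid: float, pka_base: float, ph: float = 7.4) -> float:
    """Distribution coefficient (log10) of a zwitterion at the given pH.

    logD = logP - log10(1 + 10^(pH - pKa_acid) + 10^(pKa_base - pH)).
    """
    return logp - math.log10(1.0 + 10.0 ** (ph - pka_acid) + 10.0 ** (pka_base - ph))


def kp_raw(organ: str, logd: float) -> float:
    """Unscaled tissue:plasma partition coefficient from composition."""
    fw_t, fl_t = TISSUE_COMPOSITION[organ]
    fw_p, fl_p = PLASMA_COMPOSITION
    p = 10.0**logd
    return (fw_t + p * fl_t) / (fw_p + p * fl_p)
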