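"""Centralized unit conversions.

Internal conventions, fixed at module boundaries to avoid silent drift:

* drug amounts        micromol (umol)
* concentrations      micromol/L (uM); reported plasma output in ug/mL (= mg/L)
* volumes             L
* flows / clearances  L/min
* time                minutes internally; hours at user-facing interfaces
* transporter kcat    1/min (per pmol transporter, i.e. umol/min per umol)
* Km, Ki, EC50        umol/L
"""

from __future__ import annotations

MIN_PER_H = 60.0


def mg_to_umol(mg: float, molecular_weight: float) -> float:
    """Convert a dose in mg to umol given MW in g/mol."""
    if molecular_weight <= 0:
        raise ValueError("molecular weight must be positive")
    return mg / molecular_weight * 1000.0


def umol_to_mg(umol: float, molecular_weight: float) -> float:
    return umol * molecular_weight / 1000.0


def uM_to_ug_per_mL(conc_um: float, molecular_weight: float) -> float:
    """umol/L -> ug/mL (= mg/L)."""
    return conc_um * molecular_weight / 1000.0


def ug_per_mL_to_uM(conc: float, molecular_weight: float) -> float:
    return conc * 1000.0 / molecular_weight


def mL_per_min_per_kg_to_L_per_min(cl: float, body_weight_kg: float) -> float:
    return cl * body_weight_kg / 1000.0


def h_to_min(t_h: float) -> float:
    return t_h * MIN_PER_H


def min_to_h(t_min: float) -> float:
    return t_min / MIN_PER_H
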