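"""Flow-limited whole-body ODE right-hand side.

State layout per drug (amounts in umol):

====  ===========  =====================================================
idx   compartment  notes
====  ===========  =====================================================
0     gut_lumen    oral dose target; first-order absorption and transit
1     gut          gut tissue (enterocyte pool); apical efflux to lumen
2     portal       portal-vein plasma
3     liver        linear hepatic clearance on plasma-referenced conc
4     kidney       GFR filtration + transporter-mediated secretion
5     arterial     arterial plasma
6     venous       venous plasma; IV dose target
7     lung         venous -> lung -> arterial
8     rest         lumped rest-of-body
9     urine        cumulative sink
10    feces        cumulative sink (lumen transit)
11    metabolized  cumulative sink (hepatic elimination)
====  ===========  =====================================================

Expression states (one per induction entry x organ, normalised to 1 at
baseline) are appended after the amounts when the simulated drug is itself
an inducer (auto-induction of its own clearance, and transporter induction
recorded for downstream victim runs).

Unbound, plasma-referenced concentrations drive transporter kinetics and
glomerular filtration.  The hepatic term applies the stated *plasma*
clearance to the plasma-referenced liver concentration, i.e. the unbound
concentration times an intrinsic constant CL/fu, so that the net plasma
clearance equals the configured label value in the low-extraction limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import units
from .compound import CompoundModel, InteractionEntry, TransporterKinetics
from .interaction import DEFAULT_KDEG, synthesis_rate
from .partition import PartitionSet
from .physiology import PhysiologySpec

__all__ = [
    "COMPARTMENTS",
    "IDX",
    "N_AMOUNTS",
    "transporter_flux",
    "DrugSystem",
    "NullEffects",
    "IntegrityError",
]

COMPARTMENTS = (
    "gut_lumen",
    "gut",
    "portal",
    "liver",
    "kidney",
    "arterial",
    "venous",
    "lung",
    "rest",
    "urine",
    "feces",
    "metabolized",
)
IDX = {name: i for i, name in enumerate(COMPARTMENTS)}
N_AMOUNTS = len(COMPARTMENTS)

#: Organs where efflux transporters may reside, with the lumen/urine routing.
TRANSPORTER_ORGANS = ("gut", "liver", "kidney")


class IntegrityError(RuntimeError):
    """Solver produced an inadmissible (negative) state."""


def transporter_flux(
    substrate_unbound_conc: float,
    kinetics: TransporterKinetics,
    expression_state: float,
    transporter_amount: float,
    km_app: float | None = None,
) -> float:
    """Michaelis-Menten efflux rate (umol/min).

    ``V = Kcat * E * S / (Km,app + S)`` with E the transporter amount in the
    organ (umol) times the unitless expression state.  Saturates at
    ``Kcat * E`` and is linear ``~ Kcat*E*S/Km`` at low substrate.
    """
    km = kinetics.km if km_app is None else km_app
    if km <= 0:
        raise ValueError("km_app must be > 0")
    if expression_state < 0:
        raise ValueError("expression_state must be >= 0")
    s = max(substrate_unbound_conc, 0.0)
    e = kinetics.kcat * transporter_amount * expression_state
    return e * s / (km + s)


class NullEffects:
    """No perpetrator present: unit expression, unmodified Km."""

    def expression_multiplier(self, organ: str, transporter: str, t: float) -> float:
        return 1.0

    def km_app(self, organ: str, kinetics: TransporterKinetics, t: float) -> float:
        return kinetics.km


@dataclass
class _TransporterSite:
    organ: str
    kinetics: TransporterKinetics
    amount: float  # umol of transporter at baseline expression
    sink: str  # "gut_lumen" for intestinal/biliary efflux, "urine" for renal


@dataclass
class _InductionSlot:
    organ: str
    entry: InteractionEntry
    kdeg: float


@dataclass
class DrugSystem:
    """Precomputed constants for one drug's ODE system."""

    compound: CompoundModel
    physiology: PhysiologySpec
    partitions: PartitionSet
    n_doses: int = 1
    kdeg: float = DEFAULT_KDEG

    def __post_init__(self):
        phys, comp = self.physiology, self.compound
        self.fu = comp.physchem.fu_plasma
        self.ka = phys.absorption_rate_constant(comp.intestinal_permeability)
        self.k_transit = phys.gut_transit_k
        self.cl_hepatic = units.mL_per_min_per_kg_to_L_per_min(
            comp.clearance.for_regimen(self.n_doses), phys.body_weight
        )
        self.gfr_cl = comp.clearance.gfr_fraction * phys.gfr * self.fu

        self.sites: list[_TransporterSite] = []
        for kin in comp.transporters:
            for organ in TRANSPORTER_ORGANS:
                rel = phys.expression(organ, kin.transporter_id)
                if rel <= 0:
                    continue
                amount = kin.reference_concentration * rel * phys.volumes[organ]
                sink = "urine" if organ == "kidney" else "gut_lumen"
                self.sites.append(_TransporterSite(organ, kin, amount, sink))

        # expression-turnover states carried when this drug is an inducer
        self.induction_slots: list[_InductionSlot] = []
        for entry in comp.interaction_entries(mechanism="induction"):
            organs = ("liver",) if entry.applies_to == "self" else ("gut", "kidney")
            for organ in organs:
                self.induction_slots.append(_InductionSlot(organ, entry, self.kdeg))
        self.n_states = N_AMOUNTS + len(self.induction_slots)

        self._q = phys.plasma_flows
        self._v = phys.volumes
        self._kp = self.partitions

    # -- helpers --------------------------------------------------------------

    def initial_state(self) -> np.ndarray:
        y0 = np.zeros(self.n_states)
        y0[N_AMOUNTS:] = 1.0  # expression states start at baseline
        return y0

    def conc_plasma_referenced(self, y: np.ndarray) -> dict[str, float]:
        """Plasma-referenced concentration (uM) per perfused compartment."""
        v, kp = self._v, self._kp
        return {
            "gut": y[IDX["gut"]] / (v["gut"] * kp["gut"]),
            "portal": y[IDX["portal"]] / v["portal"],
            "liver": y[IDX["liver"]] / (v["liver"] * kp["liver"]),
            "kidney": y[IDX["kidney"]] / (v["kidney"] * kp["kidney"]),
            "arterial": y[IDX["arterial"]] / v["arterial"],
            "venous": y[IDX["venous"]] / v["venous"],
            "lung": y[IDX["lung"]] / (v["lung"] * kp["lung"]),
            "rest": y[IDX["rest"]] / (v["rest"] * kp["rest"]),
        }

    def free_conc(self, y: np.ndarray, organ: str) -> float:
        """Unbound plasma-referenced concentration in one organ (uM)."""
        return self.fu * self.conc_plasma_referenced(y)[organ]

    def expression_states(self, y: np.ndarray) -> dict[tuple[str, str], float]:
        out: dict[tuple[str, str], float] = {}
        for i, slot in enumerate(self.induction_slots):
            out[(slot.organ, slot.entry.target_transporter)] = y[N_AMOUNTS + i]
        return out

    # -- right-hand side ------------------------------------------------------

    def rhs(self, t: float, y: np.ndarray, effects=None, iv_rate: float = 0.0):
        """d(state)/dt at time t.

        ``effects`` supplies the perpetrator-driven expression multipliers and
        apparent Km for this drug's transporters (None = monotherapy);
        ``iv_rate`` is a constant IV infusion rate (umol/min) for the current
        integration segment.
        """
        if effects is None:
            effects = _NULL_EFFECTS
        q, v = self._q, self._v
        c = self.conc_plasma_referenced(y)
        dy = np.zeros_like(y)

        a_lumen = max(y[IDX["gut_lumen"]], 0.0)
        absorption = self.ka * a_lumen
        transit = self.k_transit * a_lumen

        # auto-induction multiplier on this drug's own hepatic clearance
        cl_mult = 1.0
        for i, slot in enumerate(self.induction_slots):
            if slot.entry.applies_to == "self":
                cl_mult *= y[N_AMOUNTS + i]
        hepatic = self.cl_hepatic * cl_mult * c["liver"]

        filtration = self.gfr_cl * c["kidney"]

        efflux = {"gut": 0.0, "liver": 0.0, "kidney": 0.0}
        for site in self.sites:
            s_u = self.fu * c[site.organ]
            expr = effects.expression_multiplier(
                site.organ, site.kinetics.transporter_id, t
            )
            km_app = effects.km_app(site.organ, site.kinetics, t)
            efflux[site.organ] += transporter_flux(
                s_u, site.kinetics, expr, site.amount, km_app
            )

        dy[IDX["gut_lumen"]] = (
            -absorption - transit + efflux["gut"] + efflux["liver"]
        )
        dy[IDX["gut"]] = (
            absorption + q["gut"] * (c["arterial"] - c["gut"]) - efflux["gut"]
        )
        dy[IDX["portal"]] = q["gut"] * (c["gut"] - c["portal"])
        q_liver_out = q["gut"] + q["hepatic_artery"]
        dy[IDX["liver"]] = (
            q["gut"] * c["portal"]
            + q["hepatic_artery"] * c["arterial"]
            - q_liver_out * c["liver"]
            - hepatic
            - efflux["liver"]
        )
        dy[IDX["kidney"]] = (
            q["kidney"] * (c["arterial"] - c["kidney"]) - filtration - efflux["kidney"]
        )
        dy[IDX["arterial"]] = q["lung"] * c["lung"] - (
            q["gut"] + q["hepatic_artery"] + q["kidney"] + q["rest"]
        ) * c["arterial"]
        dy[IDX["venous"]] = (
            q_liver_out * c["liver"]
            + q["kidney"] * c["kidney"]
            + q["rest"] * c["rest"]
            - q["lung"] * c["venous"]
            + iv_rate
        )
        dy[IDX["lung"]] = q["lung"] * (c["venous"] - c["lung"])
        dy[IDX["rest"]] = q["rest"] * (c["arterial"] - c["rest"])
        dy[IDX["urine"]] = filtration + efflux["kidney"]
        dy[IDX["feces"]] = transit
        dy[IDX["metabolized"]] = hepatic

        # expression-turnover states driven by this drug's own free conc
        for i, slot in enumerate(self.induction_slots):
            conc_free = self.fu * c[slot.organ]
            rsyn_app = synthesis_rate(
                slot.kdeg, slot.entry.emax, slot.entry.ec50, conc_free
            )
            dy[N_AMOUNTS + i] = rsyn_app - slot.kdeg * y[N_AMOUNTS + i]

        return dy


_NULL_EFFECTS = NullEffects()
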