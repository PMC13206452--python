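"""Drug-specific parameters and in-vitro-to-in-vivo derivations.

A :class:`CompoundModel` bundles everything the engine needs to know about a
single drug: physicochemistry, hepatic/renal clearance, efflux-transporter
kinetics (ABCB1 = P-glycoprotein, ABCG2 = BCRP), and — for a perpetrator —
the interaction mechanisms it exerts on those transporters (turnover
induction, competitive inhibition, static expression fold-change).

Transporter Vmax values are derived from in-vitro assay data through the
usual two-step conversion: an intrinsic efflux clearance measured in the
linear range is converted to a maximum rate via ``Vmax = CLint * Km``, and
normalised to catalytic activity per transporter molecule via
``Kcat = Vmax / abundance``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

__all__ = [
    "PhysChem",
    "TransporterKinetics",
    "ClearanceSpec",
    "InteractionEntry",
    "CompoundModel",
    "derive_vmax",
    "derive_kcat",
    "builtin_linezolid",
    "builtin_rifampin",
    "TRANSPORTERS",
]

#: Efflux transporters carried by victim compounds.
TRANSPORTERS = ("ABCB1", "ABCG2")

#: Targets whose induction modulates a perpetrator's own hepatic clearance
#: (auto-induction), rather than a victim transporter.
SELF_CLEARANCE_TARGETS = ("OATP1B1", "AADAC")

CompoundType = Literal["monoprotic_base", "acid", "neutral"]
Mechanism = Literal["induction", "competitive_inhibition", "static_fold"]


class InvalidParameterError(ValueError):
    """A physically inadmissible model parameter."""


@dataclass(frozen=True)
class PhysChem:
    """Basic physicochemical properties.

    fu_plasma is the unbound fraction in plasma (0, 1]; logp the octanol:water
    partition coefficient used by the tissue-partitioning model.
    """

    molecular_weight: float  # g/mol
    logp: float
    compound_type: CompoundType = "neutral"
    pka: float = 7.0
    fu_plasma: float = 1.0
    solubility_water: float = 1.0  # g/L

    def __post_init__(self):
        if self.molecular_weight <= 0:
            raise InvalidParameterError("molecular_weight must be > 0")
        if not (0.0 < self.fu_plasma <= 1.0):
            raise InvalidParameterError("fu_plasma must be in (0, 1]")
        if self.solubility_water <= 0:
            raise InvalidParameterError("solubility_water must be > 0")
        if self.compound_type not in ("monoprotic_base", "acid", "neutral"):
            raise InvalidParameterError(f"unknown compound_type {self.compound_type!r}")


@dataclass(frozen=True)
class TransporterKinetics:
    """Michaelis-Menten kinetics of one efflux transporter.

    kcat is per pmol of transporter (1/min); reference_concentration is the
    transporter concentration (umol/L) in the reference organ at relative
    expression 1, so organ Vmax = kcat * ref_conc * rel_expression * V_organ.
    clint_assay / abundance_assay record the in-vitro provenance and are not
    used in simulation.
    """

    transporter_id: str
    kcat: float  # 1/min
    km: float  # umol/L
    reference_concentration: float  # umol/L
    clint_assay: float | None = None  # uL/min/mg protein
    abundance_assay: float | None = None  # pmol/mg protein

    def __post_init__(self):
        if self.kcat < 0:
            raise InvalidParameterError("kcat must be >= 0")
        if self.km <= 0:
            raise InvalidParameterError("km must be > 0")
        if self.reference_concentration <= 0:
            raise InvalidParameterError("reference_concentration must be > 0")


@dataclass(frozen=True)
class ClearanceSpec:
    """Linear hepatic plasma clearance and the glomerular filtration fraction.

    Two hepatic values support the single- vs multiple-dose clearance switch
    (steady-state clearance of the victim is reduced relative to single dose).
    gfr_fraction scales GFR * fu filtration; a value of 0 routes all renal
    elimination through active tubular secretion.
    """

    hepatic_plasma_cl: float  # mL/min/kg, single dose
    hepatic_cl_multiple_dose: float | None = None  # mL/min/kg
    gfr_fraction: float = 1.0

    def __post_init__(self):
        if self.hepatic_plasma_cl < 0:
            raise InvalidParameterError("hepatic_plasma_cl must be >= 0")
        md = self.hepatic_cl_multiple_dose
        if md is not None:
            if md < 0:
                raise InvalidParameterError("hepatic_cl_multiple_dose must be >= 0")
            if md > self.hepatic_plasma_cl:
                raise InvalidParameterError(
                    "multiple-dose clearance must not exceed single-dose clearance"
                )
        if self.gfr_fraction < 0:
            raise InvalidParameterError("gfr_fraction must be >= 0")

    def for_regimen(self, n_doses: int) -> float:
        """Hepatic plasma CL (mL/min/kg) applicable to a regimen."""
        if n_doses > 1 and self.hepatic_cl_multiple_dose is not None:
            return self.hepatic_cl_multiple_dose
        return self.hepatic_plasma_cl


@dataclass(frozen=True)
class InteractionEntry:
    """One perpetrator -> transporter mechanism.

    mechanism:
      induction              turnover model, Emax/EC50 on the synthesis rate
      competitive_inhibition Km,app = Km * (1 + I/Ki)
      static_fold            fixed expression multiplier during co-dosing

    applies_to: 'victim' for effects on the victim's transporters; 'self' for
    auto-induction of the perpetrator's own clearance pathways.
    """

    target_transporter: str
    mechanism: Mechanism
    emax: float | None = None
    ec50: float | None = None  # umol/L
    ki: float | None = None  # umol/L
    fold: float | None = None
    applies_to: Literal["victim", "self"] = "victim"

    def __post_init__(self):
        if self.mechanism == "induction":
            if self.emax is None or self.emax < 0:
                raise InvalidParameterError("induction requires emax >= 0")
            if self.ec50 is None or self.ec50 <= 0:
                raise InvalidParameterError("induction requires ec50 > 0")
        elif self.mechanism == "competitive_inhibition":
            if self.ki is None or self.ki <= 0:
                raise InvalidParameterError("inhibition requires ki > 0")
        elif self.mechanism == "static_fold":
            if self.fold is None or self.fold <= 0:
                raise InvalidParameterError("static_fold requires fold > 0")
        else:
            raise InvalidParameterError(f"unknown mechanism {self.mechanism!r}")


@dataclass(frozen=True)
class CompoundModel:
    """Complete drug parameterisation for the PBPK engine."""

    name: str
    physchem: PhysChem
    clearance: ClearanceSpec
    transporters: tuple[TransporterKinetics, ...] = ()
    interactions: tuple[InteractionEntry, ...] = ()
    intestinal_permeability: float = 0.0  # cm/min
    organ_permeability: float = 0.0  # cm/min (provenance; flow-limited model)

    def __post_init__(self):
        ids = [t.transporter_id for t in self.transporters]
        if len(ids) != len(set(ids)):
            raise InvalidParameterError("at most one kinetics entry per transporter")

    def transporter(self, transporter_id: str) -> TransporterKinetics:
        for t in self.transporters:
            if t.transporter_id == transporter_id:
                return t
        raise KeyError(transporter_id)

    def interaction_entries(
        self,
        mechanism: Mechanism | None = None,
        applies_to: str | None = None,
    ) -> tuple[InteractionEntry, ...]:
        out = self.interactions
        if mechanism is not None:
            out = tuple(e for e in out if e.mechanism == mechanism)
        if applies_to is not None:
            out = tuple(e for e in out if e.applies_to == applies_to)
        return out

    def without_transporter(self, transporter_id: str) -> "CompoundModel":
        return replace(
            self,
            transporters=tuple(
                t for t in self.transporters if t.transporter_id != transporter_id
            ),
        )


# ----------------------------------------------------------------------------
# In-vitro-to-in-vivo derivations
# ----------------------------------------------------------------------------

def derive_vmax(clint_assay: float, km: float) -> float:
    """Maximum transport rate from assay intrinsic clearance.

    Vmax = CLint * Km, with uL/min/mg * umol/L reconciling to pmol/min/mg.

    Parameters
    ----------
    clint_assay : protein-normalised intrinsic efflux clearance, uL/min/mg.
    km : Michaelis constant, umol/L.
    """
    if km <= 0:
        raise InvalidParameterError("km must be > 0")
    if clint_assay < 0:
        raise InvalidParameterError("clint_assay must be >= 0")
    # uL/min/mg * umol/L = 1e-6 L/min/mg * umol/L = pmol/min/mg
    return clint_assay * km


def derive_kcat(vmax: float, abundance: float) -> float:
    """Catalytic rate constant per transporter molecule.

    Kcat = Vmax / abundance; pmol/min/mg divided by pmol/mg gives 1/min.
    Full precision is returned; rounding is the caller's concern.
    """
    if abundance <= 0:
        raise InvalidParameterError("abundance must be > 0")
    if vmax < 0:
        raise InvalidParameterError("vmax must be >= 0")
    return vmax / abundance


# ----------------------------------------------------------------------------
# Built-in parameter sets
# ----------------------------------------------------------------------------

def builtin_linezolid() -> CompoundModel:
    """Final optimised linezolid model.

    Renal elimination is carried entirely by ABCB1/ABCG2 tubular secretion
    (gfr_fraction 0): net glomerular filtration and passive reabsorption are
    assumed to cancel, consistent with a renal plasma clearance well below
    fu * GFR.  Hepatic clearance uses the single/multiple-dose switch
    (0.65 -> 0.5 mL/min/kg at steady state).
    """
    return CompoundModel(
        name="linezolid",
        physchem=PhysChem(
            molecular_weight=337.35,
            logp=0.55,
            compound_type="monoprotic_base",
            pka=1.7,
            fu_plasma=0.69,
            solubility_water=3.0,
        ),
        clearance=ClearanceSpec(
            hepatic_plasma_cl=0.65,
            hepatic_cl_multiple_dose=0.5,
            gfr_fraction=0.0,
        ),
        transporters=(
            TransporterKinetics(
                transporter_id="ABCB1",
                kcat=72.0,
                km=51.0,
                reference_concentration=0.077,
                clint_assay=2.1,
                abundance_assay=10.3,
            ),
            TransporterKinetics(
                transporter_id="ABCG2",
                kcat=720.0,
                km=53.0,
                reference_concentration=0.025,
                clint_assay=16.0,
                abundance_assay=13.18,
            ),
        ),
        intestinal_permeability=9e-6,
        organ_permeability=9e-4,
    )


def builtin_rifampin() -> CompoundModel:
    """Rifampin perpetrator model.

    Interaction constants: ABCB1 induction Emax 2.5 / EC50 0.34 uM; ABCB1
    inhibition Ki 9.1 uM; ABCG2 inhibition Ki 14 uM; ABCG2 expression held at
    a static 1.5-fold during co-dosing.  Auto-induction of its own clearance
    pathways (OATP1B1 Emax 0.383, AADAC Emax 0.985, shared EC50 0.34 uM)
    scales rifampin's hepatic clearance at steady state.

    Rifampin's own disposition parameters (logp used as an effective
    lipophilicity for partitioning, fu, baseline hepatic clearance,
    permeability) are literature-typical defaults chosen to reproduce a
    steady-state oral profile with Cmax ~10 ug/mL, tmax ~2 h and terminal
    half-life ~2.5 h at 600 mg once daily; all are user-overridable.
    """
    return CompoundModel(
        name="rifampin",
        physchem=PhysChem(
            molecular_weight=822.94,
            logp=2.0,
            compound_type="neutral",
            pka=7.9,
            fu_plasma=0.17,
            solubility_water=1.4,
        ),
        clearance=ClearanceSpec(
            hepatic_plasma_cl=1.5,
            hepatic_cl_multiple_dose=1.5,
            gfr_fraction=1.0,
        ),
        transporters=(),
        interactions=(
            InteractionEntry("ABCB1", "induction", emax=2.5, ec50=0.34),
            InteractionEntry("ABCB1", "competitive_inhibition", ki=9.1),
            InteractionEntry("ABCG2", "competitive_inhibition", ki=14.0),
            InteractionEntry("ABCG2", "static_fold", fold=1.5),
            InteractionEntry(
                "OATP1B1", "induction", emax=0.383, ec50=0.34, applies_to="self"
            ),
            InteractionEntry(
                "AADAC", "induction", emax=0.985, ec50=0.34, applies_to="self"
            ),
        ),
        intestinal_permeability=4e-6,
        organ_permeability=9e-4,
    )
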