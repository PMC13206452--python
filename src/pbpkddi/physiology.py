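"""Reduced whole-body physiology: organ volumes, plasma flows, GFR and
transporter expression.

The organ set is deliberately small — gut lumen + gut tissue, portal vein,
liver, kidney, lung, arterial and venous plasma, and a lumped rest-of-body —
because the victim drug's disposition is governed by intestinal efflux,
hepatic clearance and renal tubular secretion; remaining distribution is
absorbed by the lumped compartment through its partition coefficient.

All concentrations are plasma-referenced (blood:plasma ratio fixed at 1 by
convention), and all flows are plasma flows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = ["PhysiologySpec", "default_adult", "TISSUE_ORGANS", "PLASMA_POOLS"]

#: Organs with tissue:plasma partitioning.
TISSUE_ORGANS = ("gut", "liver", "kidney", "lung", "rest")
#: Pure plasma pools (no partitioning).
PLASMA_POOLS = ("portal", "arterial", "venous")

#: Organs that carry efflux-transporter expression in the default physiology.
EXPRESSION_ORGANS = ("gut", "liver", "kidney")


class PhysiologyError(ValueError):
    """Inconsistent physiology configuration."""


@dataclass(frozen=True)
class PhysiologySpec:
    """Volumes (L), plasma flows (L/min), GFR and transporter expression.

    ``relative_expression[organ][transporter]`` is a unitless factor scaling
    the transporter's reference concentration in that organ;  the absolute
    transporter amount in an organ is
    ``reference_concentration * relative_expression * organ volume``.

    ``effective_intestinal_area`` (cm^2) converts a compound's intestinal
    permeability (cm/min) into a first-order absorption rate constant
    ``ka = P * A / V_lumen``; it is a calibration constant of the reduced gut
    geometry (villi-amplified), fixed once so that a high-permeability oral
    dose gives tmax in 1-2 h, and not re-tuned per compound.
    """

    body_weight: float = 73.0  # kg
    volumes: dict[str, float] = field(default_factory=dict)  # L, per compartment
    plasma_flows: dict[str, float] = field(default_factory=dict)  # L/min
    gfr: float = 0.12  # L/min
    relative_expression: dict[str, dict[str, float]] = field(default_factory=dict)
    effective_intestinal_area: float = 1.9e6  # cm^2
    gut_transit_k: float = 1.0 / 300.0  # 1/min; effective absorption-window ~5 h
    blood_plasma_ratio: float = 1.0

    def __post_init__(self):
        self.validate()

    # -- derived quantities ---------------------------------------------------

    def absorption_rate_constant(self, intestinal_permeability: float) -> float:
        """First-order absorption rate constant (1/min) from permeability (cm/min)."""
        v_lumen_cm3 = self.volumes["gut_lumen"] * 1000.0
        return intestinal_permeability * self.effective_intestinal_area / v_lumen_cm3

    def expression(self, organ: str, transporter: str) -> float:
        return self.relative_expression.get(organ, {}).get(transporter, 0.0)

    def total_plasma_flow(self) -> float:
        return sum(
            self.plasma_flows[o] for o in ("gut", "hepatic_artery", "kidney", "rest")
        )

    # -- validation -----------------------------------------------------------

    def validate(self) -> None:
        if self.body_weight <= 0:
            raise PhysiologyError("body_weight must be > 0")
        if self.gfr <= 0:
            raise PhysiologyError("gfr must be > 0")
        required_vols = ("gut_lumen",) + TISSUE_ORGANS + PLASMA_POOLS
        for organ in required_vols:
            v = self.volumes.get(organ)
            if v is None or v <= 0:
                raise PhysiologyError(f"volume for {organ!r} missing or non-positive")
        for key in ("gut", "hepatic_artery", "kidney", "rest", "lung"):
            q = self.plasma_flows.get(key)
            if q is None or q <= 0:
                raise PhysiologyError(f"plasma flow {key!r} missing or non-positive")
        # flow balance: cardiac output through the lung equals the sum of the
        # arterial outflows, which equals the venous return
        q_out = self.total_plasma_flow()
        if abs(q_out - self.plasma_flows["lung"]) > 1e-9 * q_out:
            raise PhysiologyError(
                f"flow imbalance: arterial outflow {q_out} != lung flow "
                f"{self.plasma_flows['lung']}"
            )
        for organ, table in self.relative_expression.items():
            for transporter, value in table.items():
                if value < 0:
                    raise PhysiologyError(
                        f"negative expression for {transporter} in {organ}"
                    )

    # -- scaling --------------------------------------------------------------

    def scaled_to_weight(self, weight: float, reference: float = 73.0) -> "PhysiologySpec":
        """Allometric rescale: volumes ~ W, flows and GFR ~ W^0.75.

        A stand-in for a full anthropometric model, adequate for generating
        between-subject variability around the default adult.
        """
        fv = weight / reference
        ff = fv**0.75
        return replace(
            self,
            body_weight=weight,
            volumes={k: v * fv for k, v in self.volumes.items()},
            plasma_flows={k: q * ff for k, q in self.plasma_flows.items()},
            gfr=self.gfr * ff,
        )

    def with_expression(
        self, organ: str, transporter: str, value: float
    ) -> "PhysiologySpec":
        table = {o: dict(t) for o, t in self.relative_expression.items()}
        table.setdefault(organ, {})[transporter] = value
        return replace(self, relative_expression=table)


def default_adult() -> PhysiologySpec:
    """73-kg adult with textbook organ volumes and plasma flows.

    Plasma flows assume a cardiac plasma output of 3.0 L/min.  Hepatic and
    renal ABCB1/ABCG2 relative expression: hepatic expression is zero (the
    victim drug is not excreted in bile; hepatic efflux was removed from the
    model), and the intestinal/renal factors are calibration constants of the
    reduced physiology, set once against the victim's monotherapy disposition
    anchors (oral bioavailability ~0.85, single-dose urinary recovery of
    unchanged drug ~1/3, steady-state exposure of the 600 mg twice-daily
    control arm) and then frozen; interaction outcomes are predictions, not
    calibration targets.
    """
    return PhysiologySpec(
        body_weight=73.0,
        volumes={
            "gut_lumen": 0.65,
            "gut": 1.0,
            "portal": 0.2,
            "liver": 1.7,
            "kidney": 0.31,
            "lung": 0.5,
            "arterial": 0.85,
            "venous": 1.95,
            "rest": 60.0,
        },
        plasma_flows={
            "gut": 0.55,
            "hepatic_artery": 0.25,
            "kidney": 0.60,
            "rest": 1.60,
            "lung": 3.00,
        },
        gfr=0.12,
        relative_expression={
            "gut": {"ABCB1": 0.6, "ABCG2": 0.04},
            "liver": {"ABCB1": 0.0, "ABCG2": 0.0},
            "kidney": {"ABCB1": 1.8, "ABCG2": 0.10},
        },
    )
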