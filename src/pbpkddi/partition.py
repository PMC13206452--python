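"""Tissue:plasma partition coefficients by the Rodgers-Rowland method.

Implements the mechanistic equations for neutral compounds, acids and weak
bases (pKa < 7), where tissue affinity is the sum of partitioning into
tissue water (with intracellular ionisation), neutral lipids and neutral
phospholipids, plus binding to extracellular protein inferred from the
plasma unbound fraction.  Moderate-to-strong bases (pKa >= 7) would require
acidic-phospholipid binding data and are rejected explicitly.

Kp values are plasma-referenced: Kp = Kpu * fu.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .compound import PhysChem
from .physiology import PhysiologySpec, TISSUE_ORGANS, PLASMA_POOLS

__all__ = [
    "TissueComposition",
    "PartitionSet",
    "compute_partition_coefficients",
    "vss",
    "DEFAULT_COMPOSITIONS",
]

PH_PLASMA = 7.4
PH_INTRACELLULAR = 7.0

# plasma neutral lipid / neutral phospholipid volume fractions
F_NL_PLASMA = 0.0023
F_NP_PLASMA = 0.0013


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class TissueComposition:
    """Fractional tissue composition: extracellular water, intracellular
    water, neutral lipid, neutral phospholipid, and the tissue:plasma ratio
    of the binding protein (albumin for neutrals/weak bases/acids)."""

    f_ew: float
    f_iw: float
    f_nl: float
    f_np: float
    protein_ratio: float


# Published fractional compositions; the lumped rest-of-body uses the
# muscle composition (the lumped compartment is muscle-dominated by volume).
DEFAULT_COMPOSITIONS: dict[str, TissueComposition] = {
    "gut": TissueComposition(0.282, 0.475, 0.0487, 0.0163, 0.158),
    "liver": TissueComposition(0.165, 0.573, 0.0348, 0.0252, 0.086),
    "kidney": TissueComposition(0.273, 0.483, 0.0207, 0.0162, 0.130),
    "lung": TissueComposition(0.336, 0.446, 0.0220, 0.0128, 0.212),
    "rest": TissueComposition(0.118, 0.630, 0.0238, 0.0072, 0.064),
}


@dataclass(frozen=True)
class PartitionSet:
    """Map organ -> tissue:plasma Kp with provenance."""

    kp: dict[str, float]
    provenance: str = "computed"  # or "user_supplied"

    def __post_init__(self):
        for organ, value in self.kp.items():
            if value <= 0:
                raise ConfigurationError(f"Kp for {organ!r} must be > 0")

    def __getitem__(self, organ: str) -> float:
        return self.kp[organ]


def _ionisation_factor(physchem: PhysChem, ph: float) -> float:
    """(total / neutral) concentration ratio at a given pH."""
    if physchem.compound_type == "neutral":
        return 1.0
    if physchem.compound_type == "monoprotic_base":
        return 1.0 + 10.0 ** (physchem.pka - ph)
    # acid
    return 1.0 + 10.0 ** (ph - physchem.pka)


def _kpu(physchem: PhysChem, comp: TissueComposition) -> float:
    p = 10.0**physchem.logp
    ion_iw = _ionisation_factor(physchem, PH_INTRACELLULAR)
    ion_p = _ionisation_factor(physchem, PH_PLASMA)

    lipid = (p * comp.f_nl + (0.3 * p + 0.7) * comp.f_np) / ion_p
    water = comp.f_ew + (ion_iw / ion_p) * comp.f_iw

    # protein association inferred from plasma unbound fraction
    lipid_plasma = (p * F_NL_PLASMA + (0.3 * p + 0.7) * F_NP_PLASMA) / ion_p
    ka_pr = max(1.0 / physchem.fu_plasma - 1.0 - lipid_plasma, 0.0)
    protein = ka_pr * comp.protein_ratio

    return water + lipid + protein


def compute_partition_coefficients(
    physchem: PhysChem,
    physiology: PhysiologySpec,
    user_supplied: dict[str, float] | None = None,
    compositions: dict[str, TissueComposition] | None = None,
) -> PartitionSet:
    """One Kp per tissue organ; user-supplied values override computed ones.

    Raises
    ------
    ConfigurationError
        if a tissue organ has no composition entry, or the compound is a
        moderate-to-strong base (pKa >= 7), for which this method variant
        does not apply.
    """
    if user_supplied is not None and set(user_supplied) >= set(TISSUE_ORGANS):
        return PartitionSet(
            kp={o: float(user_supplied[o]) for o in TISSUE_ORGANS},
            provenance="user_supplied",
        )

    if physchem.compound_type == "monoprotic_base" and physchem.pka >= 7.0:
        raise ConfigurationError(
            "moderate-to-strong bases (pKa >= 7) require acidic-phospholipid "
            "binding data not implemented here; supply Kp values directly"
        )

    comps = DEFAULT_COMPOSITIONS if compositions is None else compositions
    kp: dict[str, float] = {}
    for organ in TISSUE_ORGANS:
        if user_supplied is not None and organ in user_supplied:
            kp[organ] = float(user_supplied[organ])
            continue
        comp = comps.get(organ)
        if comp is None:
            raise ConfigurationError(f"no tissue composition for {organ!r}")
        kp[organ] = _kpu(physchem, comp) * physchem.fu_plasma
    provenance = "computed" if not user_supplied else "mixed"
    return PartitionSet(kp=kp, provenance=provenance)


def vss(partitions: PartitionSet, physiology: PhysiologySpec) -> float:
    """Steady-state volume of distribution (L), plasma-referenced."""
    v = sum(physiology.volumes[p] for p in PLASMA_POOLS)
    for organ in TISSUE_ORGANS:
        v += partitions[organ] * physiology.volumes[organ]
    return v
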