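"""Pre-registered simulation arms: monotherapy, standard-dose interaction
under two mechanism hypotheses, the high-dose perpetrator sweep, and
sensitivity re-runs with alternative published interaction constants.

The canonical design: rifampin once daily from day 1 through day 14
(7 pre-treatment days), linezolid 600 mg twice daily from day 8 through
day 14, PK read out over the final 12-h interval on day 14.  The matched
control arm runs the identical linezolid schedule without the perpetrator
at identical solver settings.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import yaml

from .compound import (
    CompoundModel,
    InteractionEntry,
    builtin_linezolid,
    builtin_rifampin,
)
from .evaluation import ddi_ratio
from .physiology import PhysiologySpec, default_adult
from .simulate import PKMetrics, RegimenSpec, SimulationResult, SolverOptions, run

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "run_scenario",
    "sensitivity_sets",
    "builtin_scenarios",
    "get_scenario",
    "apply_mechanism_flags",
    "apply_parameter_set",
]

MECHANISM_FLAGS = (
    "abcb1_induction",
    "abcb1_inhibition",
    "abcg2_inhibition",
    "abcg2_static_fold",
)

_FLAG_TO_ENTRY = {
    "abcb1_induction": ("ABCB1", "induction"),
    "abcb1_inhibition": ("ABCB1", "competitive_inhibition"),
    "abcg2_inhibition": ("ABCG2", "competitive_inhibition"),
    "abcg2_static_fold": ("ABCG2", "static_fold"),
}


@dataclass(frozen=True)
class ScenarioSpec:
    id: str
    victim_regimen: RegimenSpec
    perpetrator_regimen: RegimenSpec | None = None
    mechanism_flags: dict[str, bool] = field(default_factory=dict)
    parameter_set: str = "base"  # base | nilles | asaumi

    def __post_init__(self):
        unknown = set(self.mechanism_flags) - set(MECHANISM_FLAGS)
        if unknown:
            raise ValueError(f"unknown mechanism flags: {sorted(unknown)}")
        if self.parameter_set not in ("base", "nilles", "asaumi"):
            raise ValueError(f"unknown parameter set {self.parameter_set!r}")


@dataclass(frozen=True)
class ScenarioResult:
    scenario_id: str
    with_perpetrator: PKMetrics | None
    without_perpetrator: PKMetrics
    ddi_auc_ratio: float | None
    ddi_cmax_ratio: float | None
    treated: SimulationResult | None
    control: SimulationResult


def sensitivity_sets(nilles_120h: bool = False) -> dict[str, dict[str, float]]:
    """Alternative published ABCB1 interaction constants for sensitivity runs.

    The Nilles set defaults to the 96-h induction Emax (5.1); the 120-h
    value (7) is available via ``nilles_120h``.
    """
    return {
        "nilles": {
            "emax": 7.0 if nilles_120h else 5.1,
            "ec50": 1.0,
            "ki": 12.9,
        },
        "asaumi": {"emax": 4.0, "ec50": 0.0639, "ki": 0.488},
    }


def apply_parameter_set(
    perpetrator: CompoundModel, parameter_set: str, nilles_120h: bool = False
) -> CompoundModel:
    """Override the perpetrator's ABCB1 induction/inhibition constants."""
    if parameter_set == "base":
        return perpetrator
    over = sensitivity_sets(nilles_120h)[parameter_set]
    entries = []
    for e in perpetrator.interactions:
        if e.target_transporter == "ABCB1" and e.mechanism == "induction":
            e = replace(e, emax=over["emax"], ec50=over["ec50"])
        elif e.target_transporter == "ABCB1" and e.mechanism == "competitive_inhibition":
            e = replace(e, ki=over["ki"])
        entries.append(e)
    return replace(perpetrator, interactions=tuple(entries))


def apply_mechanism_flags(
    perpetrator: CompoundModel, flags: dict[str, bool]
) -> CompoundModel:
    """Drop victim-facing interaction entries whose flag is off.

    Self (auto-induction) entries always remain: they govern the
    perpetrator's own disposition, not the interaction hypothesis.
    """
    keep = []
    for e in perpetrator.interactions:
        if e.applies_to == "self":
            keep.append(e)
            continue
        key = (e.target_transporter, e.mechanism)
        flag = next((f for f, v in _FLAG_TO_ENTRY.items() if v == key), None)
        if flag is None or flags.get(flag, False):
            keep.append(e)
    return replace(perpetrator, interactions=tuple(keep))


def run_scenario(
    spec: ScenarioSpec,
    victim: CompoundModel | None = None,
    perpetrator: CompoundModel | None = None,
    physiology: PhysiologySpec | None = None,
    options: SolverOptions | None = None,
    duration_h: float | None = None,
) -> ScenarioResult:
    """Run matched treated/control simulations and return the ratio table.

    ``duration_h`` defaults to 24 h past the end of the victim's final
    dosing interval so the terminal slope is estimable.
    """
    victim = victim or builtin_linezolid()
    physiology = physiology or default_adult()
    if duration_h is None:
        tail = spec.victim_regimen.interval_h if spec.victim_regimen.n_doses > 1 else 0
        duration_h = spec.victim_regimen.last_dose_min() / 60.0 + tail + 24.0

    try:
        control = run(
            victim,
            spec.victim_regimen,
            physiology=physiology,
            duration_h=duration_h,
            options=options,
        )
        control_metrics = control.metrics()

        if spec.perpetrator_regimen is None:
            return ScenarioResult(
                spec.id, None, control_metrics, None, None, None, control
            )

        perp = perpetrator or builtin_rifampin()
        perp = apply_parameter_set(perp, spec.parameter_set)
        perp = apply_mechanism_flags(perp, spec.mechanism_flags)
        treated = run(
            victim,
            spec.victim_regimen,
            physiology=physiology,
            perpetrator=perp,
            perpetrator_regimen=spec.perpetrator_regimen,
            duration_h=duration_h,
            options=options,
        )
        treated_metrics = treated.metrics()
    except Exception as exc:
        raise RuntimeError(f"scenario {spec.id!r} failed") from exc

    return ScenarioResult(
        scenario_id=spec.id,
        with_perpetrator=treated_metrics,
        without_perpetrator=control_metrics,
        ddi_auc_ratio=ddi_ratio(treated_metrics.auc_tau, control_metrics.auc_tau),
        ddi_cmax_ratio=ddi_ratio(treated_metrics.cmax, control_metrics.cmax),
        treated=treated,
        control=control,
    )


# ----------------------------------------------------------------------------
# Shipped scenario registry
# ----------------------------------------------------------------------------

def _regimen_from_dict(d: dict) -> RegimenSpec:
    return RegimenSpec(**d)


def _load_yaml_scenarios() -> dict[str, ScenarioSpec]:
    out: dict[str, ScenarioSpec] = {}
    root = importlib.resources.files("pbpkddi") / "scenario_files"
    for entry in sorted(root.iterdir(), key=lambda p: p.name):
        if not entry.name.endswith(".yaml"):
            continue
        data = yaml.safe_load(entry.read_text())
        for item in data["scenarios"]:
            spec = ScenarioSpec(
                id=item["id"],
                victim_regimen=_regimen_from_dict(item["victim_regimen"]),
                perpetrator_regimen=(
                    _regimen_from_dict(item["perpetrator_regimen"])
                    if item.get("perpetrator_regimen")
                    else None
                ),
                mechanism_flags=item.get("mechanism_flags", {}),
                parameter_set=item.get("parameter_set", "base"),
            )
            out[spec.id] = spec
    return out


def builtin_scenarios() -> dict[str, ScenarioSpec]:
    """All shipped scenario specs, keyed by id."""
    return _load_yaml_scenarios()


def get_scenario(scenario_id: str) -> ScenarioSpec:
    try:
        return builtin_scenarios()[scenario_id]
    except KeyError:
        raise KeyError(
            f"unknown scenario {scenario_id!r}; available: "
            f"{sorted(builtin_scenarios())}"
        ) from None
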