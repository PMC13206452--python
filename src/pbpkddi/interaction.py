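"""Perpetrator effects on victim transporters.

Three mechanisms are supported, acting simultaneously where configured:

* **Induction** via a turnover model: transporter expression E(t), normalised
  to its pre-induction steady state of 1, follows
  ``dE/dt = Rsyn,app - Kdeg * E`` with
  ``Rsyn,app = Rsyn * (1 + Emax * I / (EC50 + I))`` where I is the free
  (unbound) inducer concentration local to the organ housing the
  transporter.  At constant I the steady state is ``1 + Emax*I/(EC50+I)``.
* **Competitive inhibition**: the substrate's apparent Michaelis constant
  becomes ``Km,app = Km * (1 + I / Ki)``, scaling Km while leaving Vmax
  untouched.
* **Static fold**: a fixed expression multiplier applied for the duration of
  perpetrator co-administration (used where induction was characterised only
  as an average fold-change, e.g. a 1.5-fold ABCG2 increase).

The transporter degradation constant Kdeg defaults to a 36-h turnover
half-life; with a 7-day perpetrator pre-treatment (>4 half-lives) induction
is >94% equilibrated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "DEFAULT_KDEG",
    "synthesis_rate",
    "apparent_km",
    "InductionState",
    "apply_static_fold",
]

#: Default transporter degradation rate constant, 1/min (half-life 36 h).
DEFAULT_KDEG = math.log(2.0) / 2160.0


def synthesis_rate(
    rsyn: float, emax: float, ec50: float, inducer_free_conc: float
) -> float:
    """Apparent synthesis rate in the presence of an inducer.

    Monotone increasing in the free inducer concentration, bounded by
    ``rsyn * (1 + emax)``.
    """
    if ec50 <= 0:
        raise ValueError("ec50 must be > 0")
    if inducer_free_conc < 0:
        raise ValueError("inducer concentration must be >= 0")
    return rsyn * (1.0 + emax * inducer_free_conc / (ec50 + inducer_free_conc))


def apparent_km(km: float, inhibitor_free_conc: float, ki: float) -> float:
    """Apparent Michaelis constant under competitive inhibition."""
    if km <= 0 or ki <= 0:
        raise ValueError("km and ki must be > 0")
    if inhibitor_free_conc < 0:
        raise ValueError("inhibitor concentration must be >= 0")
    return km * (1.0 + inhibitor_free_conc / ki)


@dataclass(frozen=True)
class InductionState:
    """Expression state of one (organ, transporter) pair.

    ``expression_state`` is E(t)/E0 (unitless, 1 at baseline).  The baseline
    synthesis rate equals kdeg so that the drug-free steady state is exactly
    1.  ``static_fold`` multiplies the turnover state during perpetrator
    co-administration.
    """

    organ: str
    transporter: str
    expression_state: float = 1.0
    kdeg: float = DEFAULT_KDEG
    emax: float = 0.0
    ec50: float = 1.0
    static_fold: float = 1.0

    def __post_init__(self):
        if self.expression_state <= 0:
            raise ValueError("expression_state must be > 0")
        if self.kdeg <= 0:
            raise ValueError("kdeg must be > 0")

    @property
    def rsyn_baseline(self) -> float:
        return self.kdeg

    def steady_state(self, inducer_free_conc: float) -> float:
        """Analytic steady-state expression at constant inducer concentration."""
        return synthesis_rate(1.0, self.emax, self.ec50, inducer_free_conc)

    def derivative(self, inducer_free_conc: float) -> float:
        """dE/dt for co-integration with the main system."""
        rsyn_app = synthesis_rate(self.kdeg, self.emax, self.ec50, inducer_free_conc)
        return rsyn_app - self.kdeg * self.expression_state

    def step_expression(self, inducer_free_conc: float, dt: float) -> "InductionState":
        """Advance the turnover ODE by ``dt`` minutes at constant inducer
        concentration (exact solution of the linear ODE)."""
        if dt <= 0:
            raise ValueError("dt must be > 0")
        target = self.steady_state(inducer_free_conc)
        e = target + (self.expression_state - target) * math.exp(-self.kdeg * dt)
        return replace(self, expression_state=e)

    def effective_expression(self, co_administration: bool = True) -> float:
        """Turnover state times the static fold (fold active only while the
        perpetrator is co-administered)."""
        fold = self.static_fold if co_administration else 1.0
        return self.expression_state * fold


def apply_static_fold(
    states: dict[tuple[str, str], InductionState], transporter: str, fold: float
) -> dict[tuple[str, str], InductionState]:
    """Set a static expression fold on every organ entry of one transporter.

    Raises ``KeyError`` if the transporter has no expression entry anywhere.
    """
    if fold <= 0:
        raise ValueError("fold must be > 0")
    keys = [k for k in states if k[1] == transporter]
    if not keys:
        raise KeyError(f"no expression state for transporter {transporter!r}")
    out = dict(states)
    for key in keys:
        out[key] = replace(out[key], static_fold=fold)
    return out
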