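"""Dose-event handling, ODE integration and non-compartmental PK metrics.

The coupled victim + perpetrator problem is integrated sequentially: the
perpetrator system (drug amounts plus its induction turnover states) is
integrated first with dense output, and the victim system then reads the
perpetrator's local free concentrations and expression states through a
:class:`PerpetratorEffects` provider.  The victim has no effect on the
perpetrator, so this factorisation is exact up to interpolation error of
the dense output, and guarantees that a co-administration run with all
interaction mechanisms disabled is bit-for-bit identical to monotherapy.

Integration restarts at every dose event (bolus amounts are added as state
jumps; infusions contribute a constant rate per segment).
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy import stats

from . import units
from .compound import CompoundModel, TransporterKinetics
from .core import IDX, N_AMOUNTS, DrugSystem, IntegrityError
from .partition import PartitionSet, compute_partition_coefficients
from .physiology import PhysiologySpec, default_adult

__all__ = [
    "RegimenSpec",
    "SolverOptions",
    "SimulationResult",
    "PerpetratorEffects",
    "PKMetrics",
    "run",
    "pk_metrics",
]


@dataclass(frozen=True)
class RegimenSpec:
    """Ordered dose events for one drug.

    dose is in mg, or mg/kg when ``per_kg`` is set (resolved against the
    physiology body weight at run time).
    """

    route: str  # oral | iv_bolus | iv_infusion
    dose: float
    interval_h: float = 24.0
    n_doses: int = 1
    start_time_h: float = 0.0
    infusion_duration_min: float = 30.0
    per_kg: bool = False

    def __post_init__(self):
        if self.route not in ("oral", "iv_bolus", "iv_infusion"):
            raise ValueError(f"unknown route {self.route!r}")
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        if self.n_doses < 1:
            raise ValueError("n_doses must be >= 1")
        if self.n_doses > 1 and self.interval_h <= 0:
            raise ValueError("interval must be > 0 for multi-dose regimens")

    def dose_mg(self, body_weight: float) -> float:
        return self.dose * body_weight if self.per_kg else self.dose

    def dose_times_min(self) -> list[float]:
        return [
            units.h_to_min(self.start_time_h + i * self.interval_h)
            for i in range(self.n_doses)
        ]

    def last_dose_min(self) -> float:
        return self.dose_times_min()[-1]


@dataclass(frozen=True)
class _DoseEvent:
    t: float  # min
    route: str
    amount: float  # umol
    duration: float = 0.0  # min, infusions only


@dataclass(frozen=True)
class SolverOptions:
    rtol: float = 1e-8
    atol: float = 1e-10  # umol
    method: str = "LSODA"
    grid_min: float = 5.0  # output sampling grid


def _events_for(regimen: RegimenSpec, compound: CompoundModel,
                physiology: PhysiologySpec) -> list[_DoseEvent]:
    amount = units.mg_to_umol(
        regimen.dose_mg(physiology.body_weight), compound.physchem.molecular_weight
    )
    dur = regimen.infusion_duration_min if regimen.route == "iv_infusion" else 0.0
    return [
        _DoseEvent(t, regimen.route, amount, dur) for t in regimen.dose_times_min()
    ]


class _DenseSolution:
    """Piecewise dense ODE solution over [0, t_end]."""

    def __init__(self):
        self._starts: list[float] = []
        self._sols: list = []
        self.t_end = 0.0

    def add(self, t0: float, sol) -> None:
        self._starts.append(t0)
        self._sols.append(sol)
        self.t_end = sol.t_max

    def __call__(self, t: float) -> np.ndarray:
        t = min(max(t, 0.0), self.t_end)
        i = bisect.bisect_right(self._starts, t) - 1
        i = max(i, 0)
        sol = self._sols[i]
        return sol(min(max(t, sol.t_min), sol.t_max))


@dataclass
class SimulationResult:
    """Trajectories of one drug plus bookkeeping for PK metric extraction."""

    compound: CompoundModel
    system: DrugSystem
    times_min: np.ndarray
    states: np.ndarray  # (n_times, n_states)
    dosed: np.ndarray  # cumulative administered amount (umol) at times
    regimen: RegimenSpec
    options: SolverOptions
    dense: _DenseSolution | None = None
    perpetrator: "SimulationResult | None" = None

    @property
    def time_h(self) -> np.ndarray:
        return self.times_min / 60.0

    def amounts(self, compartment: str) -> np.ndarray:
        return self.states[:, IDX[compartment]]

    def plasma_conc(self, compartment: str = "venous") -> np.ndarray:
        """Plasma concentration in ug/mL."""
        conc_um = self.amounts(compartment) / self.system.physiology.volumes[
            compartment
        ]
        return conc_um * self.compound.physchem.molecular_weight / 1000.0

    def expression_frame(self) -> pd.DataFrame:
        cols = {}
        for i, slot in enumerate(self.system.induction_slots):
            name = f"E_{slot.organ}_{slot.entry.target_transporter}"
            cols[name] = self.states[:, N_AMOUNTS + i]
        return pd.DataFrame({"time_min": self.times_min, **cols})

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format output: one row per (time, compartment)."""
        rows = []
        mw = self.compound.physchem.molecular_weight
        for name in ("gut_lumen",) + tuple(
            c for c in IDX if c not in ("gut_lumen",)
        ):
            amt = self.amounts(name)
            conc = np.full_like(amt, np.nan)
            if name in ("venous", "arterial", "portal"):
                conc = (
                    amt / self.system.physiology.volumes[name] * mw / 1000.0
                )
            rows.append(
                pd.DataFrame(
                    {
                        "time_min": self.times_min,
                        "compartment": name,
                        "amount_umol": amt,
                        "conc_ug_per_mL": conc,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def total_in_system(self) -> np.ndarray:
        return self.states[:, :N_AMOUNTS].sum(axis=1)

    def mass_balance_error(self) -> float:
        """max |dosed - accounted| / dosed over times with dose on board."""
        mask = self.dosed > 0
        if not mask.any():
            return 0.0
        err = np.abs(self.dosed[mask] - self.total_in_system()[mask])
        return float(np.max(err / self.dosed[mask]))

    def urine_fraction(
        self, t_start_h: float | None = None, t_end_h: float | None = None
    ) -> float:
        """Fraction of administered dose recovered unchanged in urine.

        With a window, the urine increment over the window is referenced to
        one dose; without, cumulative urine over the whole run is referenced
        to the total administered amount.
        """
        urine = self.amounts("urine")
        if t_start_h is None:
            return float(urine[-1] / self.dosed[-1])
        t0 = units.h_to_min(t_start_h)
        t1 = self.times_min[-1] if t_end_h is None else units.h_to_min(t_end_h)
        u0 = float(np.interp(t0, self.times_min, urine))
        u1 = float(np.interp(t1, self.times_min, urine))
        per_dose = units.mg_to_umol(
            self.regimen.dose_mg(self.system.physiology.body_weight),
            self.compound.physchem.molecular_weight,
        )
        return (u1 - u0) / per_dose

    def metrics(self, tail_for_lambda_z: bool = True) -> "PKMetrics":
        """NCA metrics over the final dosing interval."""
        dose_times = [t / 60.0 for t in self.regimen.dose_times_min()]
        tau = self.regimen.interval_h if self.regimen.n_doses > 1 else None
        m = pk_metrics(self.time_h, self.plasma_conc(), tau, dose_times)
        last = dose_times[-1]
        ae = self.urine_fraction(last, last + tau) if tau else self.urine_fraction()
        return replace(m, ae_fraction_urine=ae)


class PerpetratorEffects:
    """Expression multipliers and apparent Km driven by a perpetrator run.

    Free perpetrator concentration local to the organ housing a transporter
    (gut tissue for intestinal, kidney for renal, liver for hepatic) drives
    both the turnover states (already co-integrated in the perpetrator
    system) and the competitive-inhibition Km scaling.  Static expression
    folds are active from the first perpetrator dose onward.
    """

    def __init__(self, perp_result: SimulationResult):
        self._result = perp_result
        self._system = perp_result.system
        self._dense = perp_result.dense
        comp = perp_result.compound
        self._fu = comp.physchem.fu_plasma
        self._first_dose = perp_result.regimen.dose_times_min()[0]

        self._ind_index: dict[tuple[str, str], int] = {}
        for i, slot in enumerate(self._system.induction_slots):
            if slot.entry.applies_to == "victim":
                self._ind_index[(slot.organ, slot.entry.target_transporter)] = (
                    N_AMOUNTS + i
                )
        self._ki = {
            e.target_transporter: e.ki
            for e in comp.interaction_entries(mechanism="competitive_inhibition")
        }
        self._folds = {
            e.target_transporter: e.fold
            for e in comp.interaction_entries(mechanism="static_fold")
        }

    def _free_conc(self, organ: str, t: float) -> float:
        y = self._dense(t)
        return max(self._system.free_conc(y, organ), 0.0)

    def expression_multiplier(self, organ: str, transporter: str, t: float) -> float:
        m = 1.0
        idx = self._ind_index.get((organ, transporter))
        if idx is not None:
            m *= float(self._dense(t)[idx])
        fold = self._folds.get(transporter)
        if fold is not None and t >= self._first_dose:
            m *= fold
        return m

    def km_app(self, organ: str, kinetics: TransporterKinetics, t: float) -> float:
        ki = self._ki.get(kinetics.transporter_id)
        if ki is None:
            return kinetics.km
        return kinetics.km * (1.0 + self._free_conc(organ, t) / ki)


def _integrate(
    system: DrugSystem,
    events: list[_DoseEvent],
    duration_min: float,
    options: SolverOptions,
    effects=None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, _DenseSolution]:
    """Piecewise integration with state jumps at dose events."""
    breaks = {0.0, duration_min}
    for ev in events:
        if ev.t < duration_min:
            breaks.add(ev.t)
            if ev.route == "iv_infusion":
                breaks.add(min(ev.t + ev.duration, duration_min))
    breakpoints = sorted(breaks)

    y = system.initial_state()
    dosed_so_far = 0.0
    times = [0.0]
    states = [y.copy()]
    dosed = [0.0]
    dense = _DenseSolution()

    for t0, t1 in zip(breakpoints[:-1], breakpoints[1:]):
        for ev in events:
            if abs(ev.t - t0) < 1e-9:
                if ev.route == "oral":
                    y[IDX["gut_lumen"]] += ev.amount
                    dosed_so_far += ev.amount
                elif ev.route == "iv_bolus":
                    y[IDX["venous"]] += ev.amount
                    dosed_so_far += ev.amount
        iv_rate = 0.0
        for ev in events:
            if ev.route == "iv_infusion" and ev.t <= t0 + 1e-9 and t1 <= ev.t + ev.duration + 1e-9:
                iv_rate += ev.amount / ev.duration

        grid = np.arange(
            math.ceil(t0 / options.grid_min) * options.grid_min,
            t1,
            options.grid_min,
        )
        t_eval = np.unique(np.concatenate([[t0], grid[grid > t0 + 1e-12], [t1]]))
        sol = solve_ivp(
            lambda t, yy: system.rhs(t, yy, effects, iv_rate),
            (t0, t1),
            y,
            method=options.method,
            rtol=options.rtol,
            atol=options.atol,
            dense_output=True,
            t_eval=t_eval,
        )
        if not sol.success:
            raise IntegrityError(
                f"solver failed on [{t0}, {t1}] min: {sol.message}"
            )
        dense.add(t0, sol.sol)
        y = sol.y[:, -1].copy()
        if np.min(y[:N_AMOUNTS]) < -1e-6:
            raise IntegrityError("negative compartment amount; solver misconfigured")
        seg_dosed = dosed_so_far + np.zeros(len(sol.t))
        for ev in events:
            if ev.route == "iv_infusion" and ev.t <= t0 + 1e-9:
                frac = np.clip((sol.t - ev.t) / ev.duration, 0.0, 1.0)
                seg_dosed += ev.amount * frac
        times.extend(sol.t[1:].tolist())
        states.extend(sol.y[:, 1:].T)
        dosed.extend(seg_dosed[1:].tolist())
        if t1 == duration_min:
            dosed_so_far = seg_dosed[-1]

    return np.array(times), np.array(states), np.array(dosed), dense


def run(
    victim: CompoundModel,
    victim_regimen: RegimenSpec,
    physiology: PhysiologySpec | None = None,
    perpetrator: CompoundModel | None = None,
    perpetrator_regimen: RegimenSpec | None = None,
    duration_h: float | None = None,
    options: SolverOptions | None = None,
    victim_partitions: PartitionSet | None = None,
) -> SimulationResult:
    """Integrate the victim (and optional perpetrator) over the full regimen.

    Duration defaults to one dosing interval (or 24 h for a single dose)
    past the victim's last dose.  If the perpetrator carries no
    victim-facing interaction entries it does not enter the victim system
    at all, so an interaction-free co-administration equals monotherapy
    exactly.
    """
    physiology = physiology or default_adult()
    options = options or SolverOptions()
    if duration_h is None:
        tail = victim_regimen.interval_h if victim_regimen.n_doses > 1 else 24.0
        duration_h = victim_regimen.last_dose_min() / 60.0 + tail
    duration_min = units.h_to_min(duration_h)

    effects = None
    perp_result = None
    if perpetrator is not None:
        if perpetrator_regimen is None:
            raise ValueError("perpetrator requires a regimen")
        if perpetrator.interaction_entries(applies_to="victim"):
            perp_partitions = compute_partition_coefficients(
                perpetrator.physchem, physiology
            )
            perp_system = DrugSystem(
                perpetrator, physiology, perp_partitions,
                n_doses=perpetrator_regimen.n_doses,
            )
            p_events = _events_for(perpetrator_regimen, perpetrator, physiology)
            t, s, d, dense = _integrate(
                perp_system, p_events, duration_min, options
            )
            perp_result = SimulationResult(
                perpetrator, perp_system, t, s, d, perpetrator_regimen, options,
                dense=dense,
            )
            effects = PerpetratorEffects(perp_result)

    partitions = victim_partitions or compute_partition_coefficients(
        victim.physchem, physiology
    )
    system = DrugSystem(
        victim, physiology, partitions, n_doses=victim_regimen.n_doses
    )
    v_events = _events_for(victim_regimen, victim, physiology)
    t, s, d, dense = _integrate(system, v_events, duration_min, options, effects)
    return SimulationResult(
        victim, system, t, s, d, victim_regimen, options,
        dense=dense, perpetrator=perp_result,
    )


# ----------------------------------------------------------------------------
# Non-compartmental metrics
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class PKMetrics:
    """Exposure metrics over one dosing interval.

    auc_inf is the interval AUC plus terminal extrapolation C_end/lambda_z
    after the last dose (a superposition-consistent steady-state quantity);
    it is NaN when the terminal slope is not estimable.
    """

    auc_tau: float  # ug*h/mL
    auc_inf: float  # ug*h/mL (NaN if lambda_z not estimable)
    cmax: float  # ug/mL
    tmax: float  # h, relative to last dose
    terminal_slope: float  # lambda_z, 1/h (NaN if not estimable)
    ae_fraction_urine: float = float("nan")
    lambda_z_points: int = 0
    lambda_z_r2: float = float("nan")


class MetricsError(ValueError):
    pass


def _auc_lin_log(t: np.ndarray, c: np.ndarray) -> float:
    """Linear-up / log-down trapezoid."""
    auc = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        c1, c2 = c[i], c[i + 1]
        if c2 < c1 and c1 > 0 and c2 > 0:
            auc += dt * (c1 - c2) / math.log(c1 / c2)
        else:
            auc += dt * 0.5 * (c1 + c2)
    return auc


def _lambda_z(t: np.ndarray, c: np.ndarray) -> tuple[float, int, float]:
    """Terminal log-linear slope by best adjusted-R2 window (>= 3 points)."""
    mask = c > 0
    t, c = t[mask], c[mask]
    if len(t) < 3:
        return float("nan"), 0, float("nan")
    i_max = int(np.argmax(c))
    t_term, c_term = t[i_max + 1 :], c[i_max + 1 :]
    if len(t_term) < 3:
        t_term, c_term = t[-3:], c[-3:]
    best = (float("nan"), 0, -np.inf)
    n = len(t_term)
    for k in range(3, min(n, 40) + 1):
        tt, cc = t_term[n - k :], np.log(c_term[n - k :])
        res = stats.linregress(tt, cc)
        if res.slope >= 0:
            continue
        r2 = res.rvalue**2
        adj = 1 - (1 - r2) * (k - 1) / (k - 2)
        if adj > best[2]:
            best = (-res.slope, k, adj)
    if best[1] == 0:
        return float("nan"), 0, float("nan")
    return best


def pk_metrics(
    time_h: np.ndarray,
    conc: np.ndarray,
    dosing_interval_h: float | None = None,
    dose_times_h: list[float] | None = None,
) -> PKMetrics:
    """NCA over the final dosing interval of a concentration-time profile.

    AUC uses the linear-up/log-down trapezoid; lambda_z comes from a
    log-linear regression over the best adjusted-R2 terminal window of the
    post-window data (at least 3 points).  Concentrations in ug/mL, times in
    hours.
    """
    time_h = np.asarray(time_h, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if len(time_h) < 3:
        raise MetricsError("at least 3 samples required")
    if np.any(conc < 0):
        raise MetricsError("negative concentrations")

    t_last_dose = dose_times_h[-1] if dose_times_h else time_h[0]
    t_end = (
        t_last_dose + dosing_interval_h
        if dosing_interval_h is not None
        else time_h[-1]
    )
    in_window = (time_h >= t_last_dose - 1e-9) & (time_h <= t_end + 1e-9)
    tw, cw = time_h[in_window], conc[in_window]
    if len(tw) < 3:
        raise MetricsError("fewer than 3 samples in the dosing interval")

    auc_tau = _auc_lin_log(tw, cw)
    i_cmax = int(np.argmax(cw))
    cmax = float(cw[i_cmax])
    tmax = float(tw[i_cmax] - t_last_dose)

    post = time_h >= t_last_dose - 1e-9
    lam, npts, r2 = _lambda_z(time_h[post], conc[post])
    if math.isnan(lam):
        auc_inf = float("nan")
    else:
        c_end = float(np.interp(t_end, time_h, conc))
        auc_inf = auc_tau + c_end / lam
    return PKMetrics(
        auc_tau=float(auc_tau),
        auc_inf=float(auc_inf),
        cmax=cmax,
        tmax=tmax,
        terminal_slope=float(lam),
        lambda_z_points=int(npts),
        lambda_z_r2=float(r2),
    )
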