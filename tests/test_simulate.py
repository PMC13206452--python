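import math
from dataclasses import replace

import numpy as np
import pytest

from pbpkddi.compound import (
    ClearanceSpec,
    CompoundModel,
    InteractionEntry,
    PhysChem,
    builtin_linezolid,
    builtin_rifampin,
)
from pbpkddi.partition import PartitionSet
from pbpkddi.physiology import PhysiologySpec, TISSUE_ORGANS
from pbpkddi.simulate import (
    MetricsError,
    RegimenSpec,
    SolverOptions,
    pk_metrics,
    run,
)

from conftest import FAST, SHORT_PERP, SHORT_VICTIM, short_ddi_auc


# ----------------------------------------------------------------------------
# One-compartment closed-form oracle
# ----------------------------------------------------------------------------

def one_compartment_setup(volume=10.0, cl=0.1):
    """Degenerate the whole-body structure to a single well-mixed pool:
    tiny tissues, very high flows, unit partition coefficients."""
    tiny = 1e-3
    phys = PhysiologySpec(
        body_weight=100.0,
        volumes={
            "gut_lumen": tiny, "gut": tiny, "portal": tiny, "liver": tiny,
            "kidney": tiny, "lung": tiny, "arterial": tiny, "rest": tiny,
            "venous": volume,
        },
        plasma_flows={
            "gut": 500.0, "hepatic_artery": 500.0, "kidney": 500.0,
            "rest": 500.0, "lung": 2000.0,
        },
        gfr=1e-9,
        relative_expression={},
    )
    compound = CompoundModel(
        name="probe",
        physchem=PhysChem(molecular_weight=300.0, logp=0.0, fu_plasma=1.0),
        clearance=ClearanceSpec(hepatic_plasma_cl=cl * 1000.0 / 100.0,
                                gfr_fraction=0.0),
    )
    parts = PartitionSet(kp={o: 1.0 for o in TISSUE_ORGANS},
                         provenance="user_supplied")
    return compound, phys, parts


def test_iv_bolus_matches_one_compartment_closed_form():
    compound, phys, parts = one_compartment_setup()
    dose_mg, cl = 600.0, 0.1
    res = run(compound, RegimenSpec(route="iv_bolus", dose=dose_mg),
              physiology=phys, victim_partitions=parts, duration_h=12.0)
    v_eff = sum(v for k, v in phys.volumes.items() if k != "gut_lumen")
    d_umol = dose_mg / 300.0 * 1000.0
    t_min = res.times_min
    inside = (t_min >= 30.0)
    expected_um = d_umol / v_eff * np.exp(-cl * t_min[inside] / v_eff)
    simulated_um = res.amounts("venous")[inside] / phys.volumes["venous"]
    assert np.max(np.abs(simulated_um / expected_um - 1.0)) < 1e-3


# ----------------------------------------------------------------------------
# Driver invariants
# ----------------------------------------------------------------------------

@pytest.mark.parametrize(
    "regimen",
    [
        RegimenSpec(route="oral", dose=600.0, interval_h=12.0, n_doses=3),
        RegimenSpec(route="iv_bolus", dose=600.0),
        RegimenSpec(route="iv_infusion", dose=600.0, infusion_duration_min=30.0),
    ],
    ids=["oral_bid", "iv_bolus", "iv_infusion"],
)
def test_mass_balance_and_non_negativity(linezolid, regimen):
    res = run(linezolid, regimen, duration_h=48.0)
    assert res.mass_balance_error() < 1e-6
    assert res.states[:, :12].min() > -1e-9


def test_zero_dose_gives_zero_concentrations(linezolid):
    res = run(linezolid, RegimenSpec(route="oral", dose=0.0), duration_h=12.0)
    assert np.all(res.plasma_conc() == 0.0)


def test_dose_linearity_without_transporters(linezolid):
    """With the saturable efflux removed the model is linear: doubling the
    dose doubles the exposure."""
    linear = replace(linezolid, transporters=())
    aucs = []
    for dose in (300.0, 600.0):
        res = run(linear, RegimenSpec(route="oral", dose=dose), duration_h=48.0)
        aucs.append(res.metrics().auc_tau)
    assert aucs[1] / aucs[0] == pytest.approx(2.0, rel=1e-3)


def test_grid_independence_of_auc(linezolid):
    regimen = RegimenSpec(route="oral", dose=600.0)
    auc = {}
    for grid in (5.0, 2.5):
        res = run(linezolid, regimen, duration_h=24.0,
                  options=SolverOptions(grid_min=grid))
        auc[grid] = res.metrics().auc_tau
    assert auc[2.5] == pytest.approx(auc[5.0], rel=2e-3)


def test_repeated_run_is_deterministic(linezolid):
    regimen = RegimenSpec(route="oral", dose=600.0, interval_h=12.0, n_doses=2)
    r1 = run(linezolid, regimen, duration_h=36.0)
    r2 = run(linezolid, regimen, duration_h=36.0)
    assert np.array_equal(r1.states, r2.states)
    assert np.array_equal(r1.times_min, r2.times_min)


def test_extra_breakpoint_does_not_change_solution(linezolid):
    """Restarting the integrator mid-course (zero-amount event) reproduces
    the uninterrupted solution."""
    from pbpkddi.core import DrugSystem
    from pbpkddi.partition import compute_partition_coefficients
    from pbpkddi.physiology import default_adult
    from pbpkddi.simulate import _DoseEvent, _integrate

    phys = default_adult()
    system = DrugSystem(
        linezolid, phys, compute_partition_coefficients(linezolid.physchem, phys)
    )
    amount = 600.0 / 337.35 * 1000.0
    base = [_DoseEvent(0.0, "oral", amount)]
    split = base + [_DoseEvent(360.0, "oral", 0.0)]
    t1, s1, _, _ = _integrate(system, base, 720.0, SolverOptions())
    t2, s2, _, _ = _integrate(system, split, 720.0, SolverOptions())
    c1 = np.interp([60, 360, 600], t1, s1[:, 6])
    c2 = np.interp([60, 360, 600], t2, s2[:, 6])
    assert np.allclose(c1, c2, rtol=1e-6)


def test_single_dose_urinary_fraction_in_stated_band(single_dose_result):
    """A single oral 600 mg victim dose excretes 30-40% unchanged in urine."""
    assert 0.30 <= single_dose_result.urine_fraction() <= 0.40


def test_steady_state_reached_by_final_interval(mono_scenario):
    """Day-7 and day-6 dosing-interval AUCs agree within 1% (accumulation
    complete under twice-daily dosing)."""
    res = mono_scenario.control
    t, c = res.time_h, res.plasma_conc()

    def window_auc(a, b):
        m = (t >= a) & (t <= b)
        return np.trapezoid(c[m], t[m])

    day6 = window_auc(312.0, 324.0)
    day7 = window_auc(324.0, 336.0)
    assert day7 == pytest.approx(day6, rel=0.01)


# ----------------------------------------------------------------------------
# Perpetrator coupling
# ----------------------------------------------------------------------------

def _perp_with(rif, entries):
    keep = rif.interaction_entries(applies_to="self") + tuple(entries)
    return replace(rif, interactions=keep)


def test_interaction_off_equals_monotherapy_bitwise(linezolid, rifampin):
    """With every victim-facing mechanism disabled, co-administration and
    monotherapy produce identical trajectories."""
    inert = _perp_with(rifampin, ())
    mono = run(linezolid, SHORT_VICTIM, duration_h=72.0)
    combo = run(linezolid, SHORT_VICTIM, perpetrator=inert,
                perpetrator_regimen=SHORT_PERP, duration_h=72.0)
    assert np.array_equal(mono.states, combo.states)


def test_infinite_ki_reproduces_induction_only(linezolid, rifampin):
    induction = rifampin.interaction_entries(mechanism="induction",
                                             applies_to="victim")
    a, _ = short_ddi_auc(linezolid, _perp_with(rifampin, induction),
                         options=SolverOptions())
    weak = induction + (
        InteractionEntry("ABCB1", "competitive_inhibition", ki=1e9),
    )
    b, _ = short_ddi_auc(linezolid, _perp_with(rifampin, weak),
                         options=SolverOptions())
    assert b == pytest.approx(a, rel=1e-5)


def test_zero_emax_reproduces_inhibition_only(linezolid, rifampin):
    inhibition = rifampin.interaction_entries(
        mechanism="competitive_inhibition", applies_to="victim"
    )
    a, _ = short_ddi_auc(linezolid, _perp_with(rifampin, inhibition),
                         options=SolverOptions())
    silent = inhibition + (
        InteractionEntry("ABCB1", "induction", emax=0.0, ec50=0.34),
    )
    b, _ = short_ddi_auc(linezolid, _perp_with(rifampin, silent),
                         options=SolverOptions())
    assert b == pytest.approx(a, rel=1e-5)


def test_ddi_ratio_monotone_in_interaction_strength(linezolid, rifampin):
    """AUC ratio falls with induction Emax and rises with inhibitor potency."""
    mono = run(linezolid, SHORT_VICTIM, duration_h=72.0, options=FAST)
    auc0 = mono.metrics().auc_tau

    ratios_emax = []
    for emax in (0.0, 2.5, 5.0):
        perp = _perp_with(
            rifampin, (InteractionEntry("ABCB1", "induction", emax=emax,
                                        ec50=0.34),)
        )
        auc, _ = short_ddi_auc(linezolid, perp)
        ratios_emax.append(auc / auc0)
    assert ratios_emax[0] >= ratios_emax[1] - 1e-9
    assert ratios_emax[1] >= ratios_emax[2] - 1e-9

    ratios_ki = []
    for ki in (2.0, 9.1, 100.0):
        perp = _perp_with(
            rifampin,
            (
                InteractionEntry("ABCB1", "induction", emax=2.5, ec50=0.34),
                InteractionEntry("ABCB1", "competitive_inhibition", ki=ki),
            ),
        )
        auc, _ = short_ddi_auc(linezolid, perp)
        ratios_ki.append(auc / auc0)
    assert ratios_ki[0] >= ratios_ki[1] >= ratios_ki[2] - 1e-9


# ----------------------------------------------------------------------------
# NCA metrics
# ----------------------------------------------------------------------------

class TestPkMetrics:
    def test_constant_profile_auc(self):
        t = np.linspace(0.0, 10.0, 21)
        m = pk_metrics(t, np.full_like(t, 3.0))
        assert m.auc_tau == pytest.approx(30.0)
        assert m.cmax == 3.0

    def test_exponential_decay_extrapolates_to_closed_form(self):
        k, c0 = 0.1, 20.0
        t = np.linspace(0.0, 72.0, 289)
        m = pk_metrics(t, c0 * np.exp(-k * t))
        assert m.auc_inf == pytest.approx(c0 / k, rel=5e-3)
        assert m.terminal_slope == pytest.approx(k, rel=1e-3)

    def test_two_point_profile_rejected(self):
        with pytest.raises(MetricsError):
            pk_metrics(np.array([0.0, 1.0]), np.array([1.0, 0.5]))

    def test_negative_concentration_rejected(self):
        with pytest.raises(MetricsError):
            pk_metrics(np.array([0.0, 1.0, 2.0]), np.array([1.0, -0.1, 0.2]))

    def test_flat_tail_flags_auc_inf_missing(self):
        t = np.linspace(0.0, 10.0, 11)
        m = pk_metrics(t, np.full_like(t, 2.0))
        assert math.isnan(m.auc_inf)
        assert math.isnan(m.terminal_slope)
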