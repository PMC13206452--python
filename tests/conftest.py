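import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pbpkddi import (
    RegimenSpec,
    SolverOptions,
    builtin_linezolid,
    builtin_rifampin,
    default_adult,
    run,
)
from pbpkddi.scenarios import get_scenario, run_scenario

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


#: Relaxed solver settings for short mechanistic checks.
FAST = SolverOptions(rtol=1e-6, atol=1e-9)

#: Short interaction design used by coupling tests: 3 days of perpetrator
#: once daily, one victim dose on day 2 with a 24-h read-out.
SHORT_PERP = RegimenSpec(route="oral", dose=600.0, interval_h=24.0, n_doses=3)
SHORT_VICTIM = RegimenSpec(route="oral", dose=600.0, start_time_h=48.0)


@pytest.fixture(scope="session")
def linezolid():
    return builtin_linezolid()


@pytest.fixture(scope="session")
def rifampin():
    return builtin_rifampin()


@pytest.fixture(scope="session")
def adult():
    return default_adult()


@pytest.fixture(scope="session")
def single_dose_result(linezolid):
    """Single oral 600 mg victim dose followed for 72 h."""
    return run(linezolid, RegimenSpec(route="oral", dose=600.0), duration_h=72.0)


@pytest.fixture(scope="session")
def mono_scenario():
    """Full monotherapy control arm: 600 mg BID days 8-14."""
    return run_scenario(get_scenario("monotherapy"))


@pytest.fixture(scope="session")
def ddi_combined_scenario():
    """Full combined-mechanism interaction arm at standard perpetrator dose."""
    return run_scenario(get_scenario("ddi_combined"))


@pytest.fixture(scope="session")
def highdose_ratios():
    """Treated-arm day-14 AUCinf across the 10-40 mg/kg perpetrator sweep."""
    out = {}
    for level in (10, 20, 25, 30, 35, 40):
        res = run_scenario(get_scenario(f"highdose_{level}"))
        out[level] = res
    return out


def short_ddi_auc(victim, perpetrator, options=FAST):
    """Victim AUC under the short interaction design (helper for coupling
    and monotonicity tests)."""
    res = run(
        victim,
        SHORT_VICTIM,
        perpetrator=perpetrator,
        perpetrator_regimen=SHORT_PERP,
        duration_h=72.0,
        options=options,
    )
    return res.metrics().auc_tau, res
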