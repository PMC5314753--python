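import numpy as np
import pytest

import mhplan


@pytest.fixture(scope="session")
def cfg():
    return mhplan.load_config()


@pytest.fixture(scope="session")
def fx():
    return mhplan.syria_fixture()


@pytest.fixture(scope="session")
def benefit_setup(cfg, fx):
    """Cohorts and disorder streams for the Markov engine (built once)."""
    return mhplan.build_streams(fx, cfg.severity, cfg.benefit)


@pytest.fixture(scope="session")
def scenario_results(benefit_setup):
    """All scenario × mode runs against the partial-null comparator."""
    cohorts, streams = benefit_setup
    out = {}
    for mode in ("linear", "exponential"):
        for name in ("partial_null", "current", "target30", "target100"):
            out[(name, mode)] = mhplan.run_scenario(cohorts, streams, name, mode=mode)
    return out


def spike_cases(label: str, total: float, age: int = 30) -> mhplan.CaseCounts:
    """All prevalent cases concentrated at a single age (arithmetic checks)."""
    arr = np.zeros(101)
    arr[age] = total
    return mhplan.CaseCounts(label, arr)
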