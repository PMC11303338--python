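import pytest

from flockvalue import ScenarioSpec, load_baseline_parameters, sweep_ysm


@pytest.fixture(scope="session")
def baseline():
    """Packaged baseline parameter set (demography, prices)."""
    return load_baseline_parameters()


@pytest.fixture(scope="session")
def demo(baseline):
    return baseline[0]


@pytest.fixture(scope="session")
def prices(baseline):
    return baseline[1]


@pytest.fixture(scope="session")
def scenario_spec():
    return ScenarioSpec()


@pytest.fixture(scope="session")
def baseline_sweep(baseline, scenario_spec):
    d, p = baseline
    return sweep_ysm(d, p, scenario_spec)


@pytest.fixture(scope="session")
def fine_sweep(baseline, scenario_spec):
    d, p = baseline
    grid = tuple(round(0.30 - 0.01 * i, 2) for i in range(31))
    return sweep_ysm(d, p, scenario_spec.replace(ysm_grid=grid))
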