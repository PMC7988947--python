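import numpy as np
import pytest

from imrest import (
    CountSurface,
    simulate_incidence,
    simulate_mortality,
    simulate_population,
)
from imrest.synthetic import SyntheticConfig, expected_mortality


@pytest.fixture(scope="session")
def registry_fixture():
    """Constant-IMR synthetic registry at the default provincial scale."""
    cfg = SyntheticConfig(seed=11, years=(1988, 2013))
    mort = simulate_mortality(cfg)
    return {
        "config": cfg,
        "mortality": mort,
        "incidence": simulate_incidence(cfg, mort),
        "population": simulate_population(cfg),
    }


@pytest.fixture(scope="session")
def linear_fixture():
    """Registry whose log-IMR rises 2% per year."""
    cfg = SyntheticConfig(seed=23, years=(1988, 2013), imr_trend="linear", imr_trend_coefs=(0.02,))
    mort = simulate_mortality(cfg)
    return {
        "config": cfg,
        "mortality": mort,
        "incidence": simulate_incidence(cfg, mort),
        "population": simulate_population(cfg),
    }


@pytest.fixture(scope="session")
def noiseless_constant():
    """Exact Poisson means (no sampling noise), flat trend, fixed population."""
    cfg = SyntheticConfig(seed=0, drift=0.0, population_growth=0.0)
    _, lam = expected_mortality(cfg)
    mort = CountSurface(
        kind="mortality", sex=cfg.sex, site=cfg.site,
        years=cfg.year_array, counts=lam, ages=cfg.ages,
    )
    return {"config": cfg, "mortality": mort, "population": simulate_population(cfg)}


def scale_surface(surface: CountSurface, k: float) -> CountSurface:
    return CountSurface(
        kind=surface.kind, sex=surface.sex, site=surface.site,
        years=surface.years.copy(), counts=surface.counts * k, ages=surface.ages,
    )
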