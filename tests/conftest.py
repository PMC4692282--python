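import numpy as np
import pytest

from osclineage import (CellCycleParams, NoiseParams, OscillatorParams,
                        SyntheticSpec, limit_cycle_samples)
from osclineage.synthetic_data import parametric_sine_lineage


@pytest.fixture(scope="session")
def params() -> OscillatorParams:
    """Reference (fitted) oscillator parameter set."""
    return OscillatorParams()


@pytest.fixture(scope="session")
def cell_cycle() -> CellCycleParams:
    return CellCycleParams()


@pytest.fixture(scope="session")
def fitted_noise() -> NoiseParams:
    return NoiseParams()


@pytest.fixture(scope="session")
def init_cycle(params):
    """Limit-cycle phase samples shared across stochastic tests."""
    return limit_cycle_samples(params)


@pytest.fixture(scope="session")
def sine_trees():
    """Fast branched quasi-sinusoid fixtures for the statistics pipeline."""
    spec = SyntheticSpec(generator="parametric_sine", duration=360.0,
                         n_lineages=8, seed=7)
    return [parametric_sine_lineage(spec, seed=100 + i, lineage_id=i)
            for i in range(spec.n_lineages)]
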