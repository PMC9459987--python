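"""Shared fixtures.

``benchmark_table`` is the expensive shared fixture: a reduced-scale
(C=200) Monte-Carlo run over durations {250, 1000, 2000} ms and SNR
{5, 10, 15, 20} dB with all seven methods.  It backs the acceptance tests
and the statistical-invariant tests, and is computed once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from emgfatigue import (
    IdealSpectrum,
    StudyConfig,
    design_shaping_filter,
    run_grid,
)


@pytest.fixture(scope="session")
def spec() -> IdealSpectrum:
    return IdealSpectrum()


@pytest.fixture(scope="session")
def shaping(spec):
    return design_shaping_filter(spec, length=512)


@pytest.fixture(scope="session")
def benchmark_table():
    config = StudyConfig(
        durations_ms=(250, 1000, 2000),
        snr_db=(5.0, 10.0, 15.0, 20.0),
        realizations=200,
        master_seed=20,
    )
    return run_grid(config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
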