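import numpy as np
import pytest

from phycotox.design import AssayDesign, FourPLTruth, GroundTruth
from phycotox.endpoints import build_endpoint_table
from phycotox.exposure import build_exposure_series
from phycotox.simulate import simulate_chemistry, simulate_growth_wells

LADDER = (0.3, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0)


@pytest.fixture
def design():
    return AssayDesign("diuron", LADDER)


@pytest.fixture
def noiseless_truth():
    """Zero noise, zero chemistry loss: the pipeline should be exact."""
    return GroundTruth(model=FourPLTruth(ec50=10.0, hill=1.0),
                       noise_sd_sgr=0.0, noise_sd_yield=0.0,
                       loss_fraction=0.0, dosing_cv=0.0, seed=0)


@pytest.fixture
def noisy_truth():
    """Replicate noise at the level seen in real control wells."""
    return GroundTruth(model=FourPLTruth(ec50=10.0, hill=1.0),
                       noise_sd_sgr=0.04, noise_sd_yield=0.01,
                       loss_fraction=0.3, dosing_cv=0.02, seed=1)


@pytest.fixture
def noisy_assay(design, noisy_truth):
    wells = simulate_growth_wells(design, noisy_truth)
    chem = simulate_chemistry(design, noisy_truth)
    endpoints = build_endpoint_table(wells, "sgr")
    exposure = build_exposure_series(chem)
    return endpoints, exposure


@pytest.fixture
def noiseless_assay(design, noiseless_truth):
    wells = simulate_growth_wells(design, noiseless_truth)
    chem = simulate_chemistry(design, noiseless_truth)
    endpoints = build_endpoint_table(wells, "sgr")
    exposure = build_exposure_series(chem)
    return endpoints, exposure
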