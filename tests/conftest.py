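"""Shared fixtures: observable targets and cached calibration pipelines."""

import pytest

from gabakin.calibrate import (
    calibrate_wt,
    observed_targets,
    run_full_calibration,
)
from gabakin.params import ModelVariant


@pytest.fixture(scope="session")
def targets():
    return observed_targets()


@pytest.fixture(scope="session")
def model_I_sim_a(targets):
    """Model I calibrated to wild type, SU4/SU5 multiplier fit to singles."""
    return run_full_calibration(
        ModelVariant.I, targets, fit_su45_to="singles",
        predict=("CWT", "C4", "C5", "C45"),
    )


@pytest.fixture(scope="session")
def model_I_sim_b(targets):
    """Model I with the SU4/SU5 multiplier fit to the double mutant."""
    return run_full_calibration(
        ModelVariant.I, targets, fit_su45_to="C45", predict=("C4", "C5", "C45")
    )


@pytest.fixture(scope="session")
def model_II_full(targets):
    return run_full_calibration(
        ModelVariant.II, targets, max_nfev=120,
        predict=("CWT", "C3", "C4", "C45", "C345"),
    )


@pytest.fixture(scope="session")
def model_III_full(targets):
    return run_full_calibration(
        ModelVariant.III, targets, couplings=(100.0, 10.0), max_nfev=120,
        predict=("CWT", "C3", "C4", "C5", "C34", "C35", "C45", "C345"),
    )


@pytest.fixture(scope="session")
def model_III_wt(targets):
    """Wild-type-only model III calibration at the best couplings."""
    return calibrate_wt(ModelVariant.III, targets["CWT"], (100.0, 10.0))


@pytest.fixture(scope="session")
def concerted_full(targets):
    """Concerted variant calibrated on wild type and the SU4/SU5 singles."""
    sub = {c: targets[c] for c in ("CWT", "C4", "C5")}
    return run_full_calibration(
        ModelVariant.CONCERTED, sub, predict=("C4", "C5", "C45")
    )
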