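import pandas as pd
import pytest

from ptim.core import binarize_targets, scale_screen
from ptim.screens import Drug, ScreenResult, TargetProfile
from ptim.synthetic import GroundTruth, simulate_screen


@pytest.fixture
def small_screen():
    """Hand-built 4-drug / 3-target screen with one obvious sensitive block."""
    drugs = {
        "d1": Drug("d1", "one", max_tested_dose=10_000.0, cmax=100.0),
        "d2": Drug("d2", "two", max_tested_dose=10_000.0, cmax=100.0),
        "d3": Drug("d3", "three", max_tested_dose=10_000.0, cmax=100.0),
        "d4": Drug("d4", "four", max_tested_dose=10_000.0, cmax=100.0),
    }
    profiles = [
        TargetProfile("d1", "A", 10.0),
        TargetProfile("d2", "A", 20.0),
        TargetProfile("d2", "B", 50.0),
        TargetProfile("d3", "B", 30.0),
        TargetProfile("d4", "C", 40.0),
    ]
    screen = ScreenResult(
        screen_id="s", model_id="m",
        ic50={"d1": 10.0, "d2": 50.0, "d3": 100_000.0, "d4": 100_000.0},
    )
    return drugs, profiles, screen


@pytest.fixture
def noiseless_gt():
    return GroundTruth(seed=7, sigma_log10=0.0)


@pytest.fixture
def noiseless_instance(noiseless_gt):
    drugs, profiles, screen, truth = simulate_screen(noiseless_gt)
    y = scale_screen(screen, drugs)
    matrix = binarize_targets(profiles, drugs)
    return noiseless_gt, drugs, profiles, screen, truth, y, matrix


def write_tsv(path, rows, columns):
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
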