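import numpy as np
import pytest

from cinerisk.io import CineSequence, CohortTable, SurvivalRecord, crop_and_resample
from cinerisk.phantom import PhantomParams, SurvivalSimConfig, generate_phantom_sequence, sample_cohort, simulate_survival

# test-scale geometry: 32 px at 8.8 mm spacing covers the same ~280 mm field
# of view as the production 128 px / 2.2 mm grid
TEST_SIZE = 32
TEST_SPACING = 8.8


@pytest.fixture(scope="session")
def phantom_params():
    return PhantomParams(lv_ef=0.30, noise_sd=0.02, n_frames=8)


@pytest.fixture(scope="session")
def small_sequence(phantom_params):
    return generate_phantom_sequence(
        phantom_params, spacing_mm=TEST_SPACING, size_px=TEST_SIZE, seed=3, subject_id="S0"
    )


@pytest.fixture(scope="session")
def small_cohort():
    """30 rendered subjects with simulated outcomes, normalized for training."""
    raw = sample_cohort(
        30, seed=7, spacing_mm=TEST_SPACING, size_px=TEST_SIZE, noise_sd=0.02, n_frames=8
    )
    seqs = [
        crop_and_resample(s, out_size=TEST_SIZE, out_spacing_mm=TEST_SPACING)
        for _, _, s in raw
    ]
    surv = simulate_survival(
        raw, SurvivalSimConfig(log_hazard_coeffs={"lv_ef": -1.0}, seed=8)
    )
    return raw, seqs, surv


@pytest.fixture()
def toy_survival():
    recs = [
        SurvivalRecord("a", 1.0, 1, {"x": 0.1}),
        SurvivalRecord("b", 2.0, 0, {"x": -0.4}),
        SurvivalRecord("c", 3.0, 1, {"x": 1.2}),
        SurvivalRecord("d", 4.0, 2, {"x": 0.0}),
    ]
    return CohortTable(records=recs, outcome_label="VA")


def rng(seed=0):
    return np.random.default_rng(seed)
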