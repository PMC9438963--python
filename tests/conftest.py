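import logging

import numpy as np
import pytest

import cpmkit as ck


@pytest.fixture(autouse=True)
def _quiet_fold_warnings():
    # degenerate-fold fallbacks are expected in tiny null cohorts
    logging.getLogger("cpmkit").setLevel(logging.ERROR)
    yield


@pytest.fixture
def null_dataset():
    return ck.generate_null_cohort(12, 30, seed=11).to_dataset()


@pytest.fixture
def planted_cohort():
    noise = ck.calibrate_noise_sd(10, 1.0, target_r2=0.5)
    return ck.generate_cohort(20, 30, 10, effect_scale=1.0, noise_sd=noise, seed=21)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
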