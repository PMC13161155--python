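import numpy as np
import pytest

import ramancell as rc


@pytest.fixture(scope="session")
def grid():
    """The standard 1761-channel fingerprint grid (600-1800 cm^-1)."""
    return np.linspace(600.0, 1800.0, 1761)


@pytest.fixture(scope="session")
def small_grid():
    return np.linspace(600.0, 1800.0, 400)


@pytest.fixture
def tiny_set():
    """3 samples x 5 channels with CR/NR labels."""
    w = np.array([600.0, 700.0, 800.0, 900.0, 1000.0])
    m = np.array(
        [
            [0.1, 0.5, 1.0, 0.5, 0.1],
            [0.2, 0.6, 0.9, 0.4, 0.2],
            [0.3, 0.4, 0.8, 0.6, 0.15],
        ]
    )
    meta = [
        rc.SampleMeta("s1", "p1", "CR"),
        rc.SampleMeta("s2", "p1", "CR"),
        rc.SampleMeta("s3", "p2", "NR"),
    ]
    return rc.SpectraSet(w, m, meta)


@pytest.fixture(scope="session")
def clean_cohort():
    """Small noiseless/interferent-free synthetic cohort with truth."""
    cfg = rc.SyntheticConfig(
        grid=np.linspace(600.0, 1800.0, 400),
        n_patients=3,
        cells_per_group={"CR": 30, "NR": 30},
        baseline_params=rc.BaselineParams(amplitude=0.0),
        glass_params=rc.GlassParams(amplitude=0.0),
        noise_sd=0.0,
        seed=11,
    )
    return rc.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """Full default-condition cohort (interferents on), small size for speed."""
    cfg = rc.SyntheticConfig(
        n_patients=4,
        cells_per_group={"CR": 60, "NR": 60},
        seed=23,
    )
    ds, truth = rc.simulate_dataset(cfg)
    return cfg, ds, truth
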