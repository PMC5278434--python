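import numpy as np
import pytest

import toadhop as th


@pytest.fixture(scope="session")
def noisefree_cohort():
    """54 noise-free hops (6 animals x 3 treatments x 3) with ground truth,
    analyzed with an interpolating spline."""
    cfg = th.HopSimConfig(marker_noise_sd=0.0, tracking_noise_sd=0.0,
                          hops_per_treatment=(3, 3))
    recordings, truth = th.simulate_cohort(cfg, seed=2)
    metrics, series, info = th.analyze_recordings(
        recordings, th.PipelineConfig(smoothing=0.0))
    return recordings, truth, metrics, info


@pytest.fixture(scope="session")
def noisy_cohort():
    """One default-noise cohort (8 hops per animal x treatment), analyzed."""
    cfg = th.HopSimConfig(hops_per_treatment=(8, 8))
    recordings, truth = th.simulate_cohort(cfg, seed=1)
    metrics, series, info = th.analyze_recordings(recordings)
    return recordings, truth, metrics, info


@pytest.fixture()
def single_hop():
    """A clean flat 45-degree hop and its ground truth."""
    cfg = th.HopSimConfig(marker_noise_sd=0.0, tracking_noise_sd=0.0)
    rng = np.random.default_rng(11)
    return th.simulate_hop(cfg, 0.0, rng, treatment="flat",
                           takeoff_speed=1.7, takeoff_angle=45.0)
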