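"""Shared fixtures: kept session-scoped where generation is expensive."""

import numpy as np
import pytest

from segconn import synthdata


@pytest.fixture(scope="session")
def sensor_small():
    """Small sensor model for source-analysis tests (fewer voxels than default)."""
    return synthdata.make_sensor_model(n_channels=40, grid_shape=6,
                                       edge_length=0.5,
                                       seed=np.random.default_rng(11))


@pytest.fixture(scope="session")
def sensor_default():
    """Default-scale sensor model (60 channels, 8^3 grid)."""
    return synthdata.make_sensor_model(seed=np.random.default_rng(7))


@pytest.fixture(scope="session")
def eeg_cohort():
    """Small cohort with EEG, shared by marker/spectral/pipeline tests."""
    cfg = synthdata.CohortConfig(n_subjects=6, n_intervals=400,
                                 n_eeg_intervals=150, snr=5.0)
    return synthdata.generate_cohort(cfg, seed=123)


def dipole_epochs(sensor, voxel, orientation, n_trials=8, n_samples=301,
                  fs=300.0, f0=20.0, snr=10.0, seed=0, window=(-0.5, 0.5)):
    """Synthesize epochs carrying a single oscillating dipole plus white noise.

    Returns an EpochSet shaped like the boundary-interval epochs the source
    stage consumes.
    """
    from segconn.markers import EpochSet

    rng = np.random.default_rng(seed)
    o = np.asarray(orientation, float)
    o = o / np.linalg.norm(o)
    gain = sensor.leadfield[:, voxel, :] @ o
    t = np.arange(n_samples) / fs
    data = np.empty((n_trials, sensor.n_channels, n_samples))
    for k in range(n_trials):
        phase = rng.uniform(0, 2 * np.pi)
        amp = 1.0 + 0.2 * rng.standard_normal()
        src = amp * np.sin(2 * np.pi * f0 * t + phase)
        sig = gain[:, None] * src[None, :]
        sig_rms = np.sqrt(np.mean(sig ** 2))
        noise = rng.standard_normal((sensor.n_channels, n_samples))
        data[k] = sig + (sig_rms / snr) * noise
    return EpochSet(epochs=data, window=window, fs=fs, condition="BI")
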