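"""Tests for the DICS/LCMV source-analysis stage."""

import numpy as np
import pytest

from segconn.markers import EpochSet
from segconn.source import (DICSBeamformer, LCMVBeamformer, NAIMap,
                            SourceCluster, csd, dics_scan, lcmv_timecourses,
                            threshold_and_cluster)
from segconn.spectral import ALPHA, BETA, THETA

from conftest import dipole_epochs


# ---------------------------------------------------------------------------
# Cross-spectral density
# ---------------------------------------------------------------------------

def test_csd_matches_direct_formula():
    """csd() equals the trial/bin-averaged outer product computed by loops."""
    rng = np.random.default_rng(1)
    fs = 300.0
    data = rng.standard_normal((4, 3, 301))
    epochs = EpochSet(epochs=data, window=(-0.5, 0.5), fs=fs)
    C = csd(epochs, BETA, window=(-0.5, 0.5))

    freqs = np.fft.rfftfreq(301, d=1 / fs)
    bins = np.flatnonzero((freqs >= 15.0) & (freqs <= 30.0))
    ref = np.zeros((3, 3), dtype=complex)
    for t in range(4):
        X = np.fft.rfft(data[t], axis=1) / 301
        for b in bins:
            ref += np.outer(X[:, b], np.conj(X[:, b]))
    ref /= 4 * bins.size
    np.testing.assert_allclose(C, ref, atol=1e-12)
    # Hermitian with non-negative diagonal
    np.testing.assert_allclose(C, C.conj().T, atol=1e-14)
    assert np.all(np.real(np.diag(C)) >= 0)


def test_csd_identical_channels_fully_coherent():
    rng = np.random.default_rng(2)
    x = rng.standard_normal((6, 1, 301))
    epochs = EpochSet(epochs=np.repeat(x, 2, axis=1), window=(-0.5, 0.5), fs=300.0)
    C = csd(epochs, BETA)
    coh = np.abs(C[0, 1]) / np.sqrt(np.real(C[0, 0]) * np.real(C[1, 1]))
    assert coh == pytest.approx(1.0, abs=1e-12)


def test_csd_validation():
    empty = EpochSet(epochs=np.empty((0, 3, 301)), window=(-0.5, 0.5), fs=300.0)
    with pytest.raises(ValueError, match="at least one"):
        csd(empty, BETA)
    # 31 samples at 300 Hz -> ~9.7 Hz bin spacing, nothing inside theta 4-7 Hz
    short = EpochSet(epochs=np.zeros((1, 3, 31)), window=(-0.05, 0.05), fs=300.0)
    with pytest.raises(ValueError, match="no resolvable"):
        csd(short, THETA, window=(-0.05, 0.05))


# ---------------------------------------------------------------------------
# DICS scan
# ---------------------------------------------------------------------------

def test_dics_white_noise_nai_flat(sensor_small):
    """Sensor white noise yields an NAI map close to 1 + reg everywhere."""
    rng = np.random.default_rng(3)
    data = rng.standard_normal((150, sensor_small.n_channels, 301))
    epochs = EpochSet(epochs=data, window=(-0.5, 0.5), fs=300.0)
    C = csd(epochs, BETA)
    nai = dics_scan(C, sensor_small.leadfield, sensor_small.grid,
                    sensor_small.edge_length, reg=0.05)
    assert nai.values.max() / nai.values.min() < 1.5
    assert np.median(nai.values) == pytest.approx(1.05, rel=0.3)


def test_dics_localizes_single_dipole(sensor_small):
    """The NAI peak lands within one grid edge of a planted dipole."""
    rng = np.random.default_rng(4)
    for _ in range(5):
        voxel = int(rng.integers(sensor_small.grid.shape[0]))
        epochs = dipole_epochs(sensor_small, voxel, rng.standard_normal(3),
                               n_trials=20, snr=10.0, seed=int(rng.integers(2**31)))
        C = csd(epochs, BETA)
        nai = dics_scan(C, sensor_small.leadfield, sensor_small.grid,
                        sensor_small.edge_length)
        dist = np.linalg.norm(sensor_small.grid[nai.peak_voxel]
                              - sensor_small.grid[voxel])
        assert dist <= sensor_small.edge_length + 1e-9


def test_dics_scale_invariance(sensor_small):
    epochs = dipole_epochs(sensor_small, 42, [1.0, 0.5, 0.2], seed=5)
    C = csd(epochs, BETA)
    a = dics_scan(C, sensor_small.leadfield, sensor_small.grid,
                  sensor_small.edge_length)
    b = dics_scan(100.0 * C, sensor_small.leadfield, sensor_small.grid,
                  sensor_small.edge_length)
    np.testing.assert_allclose(a.values, b.values, rtol=1e-6)


def test_dics_requires_hermitian_csd(sensor_small):
    C = np.eye(sensor_small.n_channels) + 0j
    C[0, 1] = 1.0   # not mirrored
    with pytest.raises(ValueError, match="Hermitian"):
        dics_scan(C, sensor_small.leadfield, sensor_small.grid,
                  sensor_small.edge_length)


# ---------------------------------------------------------------------------
# Thresholding and clustering
# ---------------------------------------------------------------------------

def _flat_grid_nai(values_2d, edge=1.0):
    """NAIMap on a 2-D integer grid (z = 0), values given as a 2-D array."""
    h, w = values_2d.shape
    grid = np.array([[x, y, 0.0] for y in range(h) for x in range(w)], float)
    return NAIMap(values=values_2d.ravel(), band=BETA, grid=grid,
                  edge_length=edge), grid


def test_threshold_and_cluster_two_hotspots():
    vals = np.ones((6, 12))
    vals[1:3, 1:3] = 10.0       # hotspot A (4 voxels) in region 0
    vals[3:5, 8:10] = 12.0      # hotspot B (4 voxels) in region 1
    nai, grid = _flat_grid_nai(vals)
    atlas = np.where(grid[:, 0] < 6, 0, 1)
    cs = threshold_and_cluster(nai, atlas, quantile=0.85, min_size=4,
                               per_region=True)
    assert len(cs) == 2
    # clusters sorted by mean NAI: B first
    assert cs.clusters[0].regions == (1,)
    assert cs.clusters[1].regions == (0,)
    assert cs.clusters[0].mean_nai == pytest.approx(12.0)
    assert len(cs.clusters[0].voxels) == 4
    # peak voxel carries the cluster maximum
    for c in cs.clusters:
        assert nai.values[c.peak_voxel] == max(nai.values[v] for v in c.voxels)


def test_threshold_and_cluster_per_region_splits_boundary():
    """A hotspot straddling an atlas boundary is split in per-region mode."""
    vals = np.ones((4, 8))
    vals[1:3, 3:5] = 9.0        # 2x2 hotspot across the region boundary at x=4
    nai, grid = _flat_grid_nai(vals)
    atlas = np.where(grid[:, 0] < 4, 0, 1)
    pooled = threshold_and_cluster(nai, atlas, quantile=0.8, min_size=2)
    assert len(pooled) == 1 and pooled.clusters[0].regions == (0, 1)
    split = threshold_and_cluster(nai, atlas, quantile=0.8, min_size=2,
                                  per_region=True)
    assert all(len(c.regions) == 1 for c in split.clusters)


def test_threshold_and_cluster_small_group_dropped():
    vals = np.ones((5, 5))
    vals[0, 0] = 50.0           # single supra-threshold voxel < min_size
    nai, grid = _flat_grid_nai(vals)
    atlas = np.zeros(25, dtype=int)
    cs = threshold_and_cluster(nai, atlas, quantile=0.9, min_size=4)
    assert len(cs) == 0


def test_threshold_and_cluster_ignores_unlabeled():
    vals = np.ones((4, 4))
    vals[:2, :2] = 20.0
    nai, grid = _flat_grid_nai(vals)
    atlas = np.full(16, -1)     # nothing labeled: hotspot cannot cluster
    cs = threshold_and_cluster(nai, atlas, quantile=0.5, min_size=2)
    assert len(cs) == 0


# ---------------------------------------------------------------------------
# LCMV virtual channels
# ---------------------------------------------------------------------------

def _two_dipole_epochs(sensor, voxels, n_trials=30, n_samples=301, fs=300.0,
                       snr=10.0, seed=0):
    """Two independent narrowband dipoles; returns (EpochSet, sources)."""
    rng = np.random.default_rng(seed)
    orientations = [np.array([1.0, 0.2, -0.1]), np.array([-0.3, 1.0, 0.2])]
    gains = []
    for v, o in zip(voxels, orientations):
        o = o / np.linalg.norm(o)
        gains.append(sensor.leadfield[:, v, :] @ o)
    t = np.arange(n_samples) / fs
    data = np.zeros((n_trials, sensor.n_channels, n_samples))
    sources = np.zeros((2, n_trials, n_samples))
    for k in range(n_trials):
        for s, g in enumerate(gains):
            src = np.sin(2 * np.pi * 20.0 * t + rng.uniform(0, 2 * np.pi))
            sources[s, k] = src
            data[k] += g[:, None] * src[None, :]
        sig_rms = np.sqrt(np.mean(data[k] ** 2))
        data[k] += (sig_rms / snr) * rng.standard_normal((sensor.n_channels,
                                                          n_samples))
    return EpochSet(epochs=data, window=(-0.5, 0.5), fs=fs), sources


def _cluster_at(voxel, region=0):
    return SourceCluster(voxels=(voxel,), regions=(region,), peak_voxel=voxel,
                         mean_nai=1.0)


def test_lcmv_reconstructs_waveform(sensor_small):
    """The virtual channel at the true voxel correlates > 0.95 with the source."""
    voxels = (30, 180)          # well-separated grid corners
    epochs, sources = _two_dipole_epochs(sensor_small, voxels, seed=6)
    vcs = lcmv_timecourses(epochs, sensor_small.leadfield,
                           [_cluster_at(v) for v in voxels],
                           compute_beta_power=False)
    for s, vc in enumerate(vcs):
        r = np.corrcoef(vc.timecourses.ravel(), sources[s].reshape(30, -1).ravel())[0, 1]
        assert abs(r) > 0.95
        # cross-talk with the other, independent source stays low
        r_x = np.corrcoef(vc.timecourses.ravel(),
                          sources[1 - s].reshape(30, -1).ravel())[0, 1]
        assert abs(r_x) < 0.3
        assert np.linalg.norm(vc.orientation) == pytest.approx(1.0)


def test_lcmv_beta_power_trace(sensor_small):
    epochs = dipole_epochs(sensor_small, 100, [0.5, 1.0, 0.1], n_trials=6,
                           seed=8)
    vcs = lcmv_timecourses(epochs, sensor_small.leadfield, [_cluster_at(100)])
    vc = vcs[0]
    assert vc.beta_power.shape == vc.timecourses.shape
    assert np.all(vc.beta_power >= 0)
    assert vc.beta_power.mean() > 0


# ---------------------------------------------------------------------------
# Estimator wrappers
# ---------------------------------------------------------------------------

def test_dics_estimator_end_to_end(sensor_small):
    epochs = dipole_epochs(sensor_small, 91, [1.0, 0.0, 0.3], n_trials=20,
                           snr=10.0, seed=9)
    est = DICSBeamformer(sensor_model=sensor_small, quantile=0.9, min_size=3,
                         per_region=True)
    assert est.get_params()["quantile"] == 0.9
    est.fit(epochs)
    assert est.nai_map_.values.shape == (sensor_small.grid.shape[0],)
    cs = est.cluster()
    assert len(cs) >= 1
    top = cs.clusters[0]
    dist = np.linalg.norm(sensor_small.grid[top.peak_voxel]
                          - sensor_small.grid[91])
    assert dist <= 2 * sensor_small.edge_length + 1e-9

    lcmv = LCMVBeamformer(sensor_model=sensor_small, clusters=cs.clusters,
                          compute_beta_power=False).fit(epochs)
    tcs = lcmv.transform()
    assert tcs.shape[0] == len(cs)
    assert tcs.shape[1] == epochs.n_trials


def test_dics_estimator_requires_sensor_model():
    with pytest.raises(ValueError, match="sensor_model"):
        DICSBeamformer().fit(None)
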