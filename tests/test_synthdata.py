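"""Tests for the synthetic-data generator."""

import numpy as np
import pytest

from segconn import synthdata
from segconn.synthdata import (CohortConfig, GroundTruthConnectivity,
                               InstabilityError, MovieCoding, NonlinearTerm,
                               SubjectProfile, beta_oscillator_truth,
                               boundary_envelope, generate_cohort,
                               generate_movie_coding, generate_responses,
                               project_sources, simulate_nonlinear_mvar)


# ---------------------------------------------------------------------------
# Movie coding
# ---------------------------------------------------------------------------

def test_movie_coding_total_and_distribution():
    coding = generate_movie_coding(978, seed=5)
    assert coding.n_intervals == 978
    p = synthdata.default_change_distribution()
    observed = np.bincount(coding.change_counts, minlength=6)
    # each category count within 3 binomial SDs of its expectation
    expect = 978 * p
    sd = np.sqrt(978 * p * (1 - p))
    assert np.all(np.abs(observed - expect) <= 3 * sd)


def test_movie_coding_degenerate_distribution():
    coding = generate_movie_coding(100, distribution=(1, 0, 0, 0, 0, 0), seed=0)
    assert np.all(coding.change_counts == 0)


def test_movie_coding_determinism():
    a = generate_movie_coding(200, seed=42)
    b = generate_movie_coding(200, seed=42)
    assert np.array_equal(a.change_counts, b.change_counts)


def test_movie_coding_validation():
    with pytest.raises(ValueError):
        generate_movie_coding(0)
    with pytest.raises(ValueError):
        generate_movie_coding(10, distribution=(0.5, 0.2))  # does not sum to 1
    with pytest.raises(ValueError):
        MovieCoding(change_counts=np.array([1, -2, 0]))


def test_interval_of_half_open():
    coding = MovieCoding(change_counts=np.zeros(5, dtype=int))
    assert coding.interval_of(0.0) == 0
    assert coding.interval_of(1.999) == 0
    assert coding.interval_of(2.0) == 1
    assert coding.duration == 10.0


# ---------------------------------------------------------------------------
# Responses
# ---------------------------------------------------------------------------

def test_generate_responses_flat_model():
    coding = generate_movie_coding(5000, seed=1)
    profile = SubjectProfile(subject_id="s", age=13.0, random_intercept=0.0,
                             true_slope=0.0)
    responses, times = generate_responses(coding, profile, seed=2)
    rate = responses.mean()
    assert abs(rate - 0.5) < 3 * np.sqrt(0.25 / 5000)
    assert np.all(np.diff(times) >= 0)
    assert times.size == responses.sum()


def test_generate_responses_saturation():
    coding = generate_movie_coding(2000, seed=1)
    profile = SubjectProfile(subject_id="s", age=13.0, random_intercept=-50.0,
                             true_slope=0.30)
    responses, times = generate_responses(coding, profile, seed=3)
    assert responses.sum() == 0
    assert times.size == 0


def test_generate_responses_glm_recovery():
    """Pooled GLM over many replicate timelines recovers the planted law."""
    import statsmodels.api as sm

    rng_seed = 7
    profile = SubjectProfile(subject_id="s", age=13.0, random_intercept=-3.36,
                             true_slope=0.30)
    xs, ys = [], []
    for rep in range(30):
        coding = generate_movie_coding(978, seed=1000 + rep)
        responses, _ = generate_responses(coding, profile, seed=rng_seed + rep)
        xs.append(coding.change_counts.astype(float))
        ys.append(responses.astype(float))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    res = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit()
    lo, hi = res.conf_int()[0]
    assert lo <= -3.36 <= hi
    lo, hi = res.conf_int()[1]
    assert lo <= 0.30 <= hi


# ---------------------------------------------------------------------------
# Nonlinear MVAR simulation
# ---------------------------------------------------------------------------

def test_mvar_white_noise():
    truth = GroundTruthConnectivity(linear_coeffs=np.zeros((2, 2, 1)))
    x = simulate_nonlinear_mvar(truth, 20000, seed=0)
    assert x.shape == (2, 20000)
    assert np.allclose(x.var(axis=1), 1.0, atol=0.06)
    r = np.corrcoef(x)[0, 1]
    assert abs(r) < 0.03


def test_mvar_chain_yule_walker():
    """x2(n) = 0.5 x1(n-1) + e2 with x1 white: lag-1 corr = 0.5/sqrt(1.25)."""
    A = np.zeros((2, 2, 1))
    A[1, 0, 0] = 0.5
    truth = GroundTruthConnectivity(linear_coeffs=A)
    x = simulate_nonlinear_mvar(truth, 100000, seed=1)
    fwd = np.corrcoef(x[1, 1:], x[0, :-1])[0, 1]
    rev = np.corrcoef(x[0, 1:], x[1, :-1])[0, 1]
    assert abs(fwd - 0.5 / np.sqrt(1.25)) < 0.02
    assert abs(rev) < 0.02


def test_mvar_nonlinear_term():
    A = np.zeros((2, 2, 1))
    term = NonlinearTerm(target=1, source=0, lag=1, form="square", gain=0.4)
    truth = GroundTruthConnectivity(linear_coeffs=A, nonlinear_terms=(term,))
    x = simulate_nonlinear_mvar(truth, 100000, seed=2)
    quad = np.corrcoef(x[1, 1:], x[0, :-1] ** 2)[0, 1]
    lin = np.corrcoef(x[1, 1:], x[0, :-1])[0, 1]
    assert quad > abs(lin)
    assert quad > 0.2


def test_mvar_unstable_linear_rejected():
    A = np.zeros((1, 1, 1))
    A[0, 0, 0] = 1.05
    with pytest.raises(ValueError, match="unstable"):
        GroundTruthConnectivity(linear_coeffs=A)


def test_mvar_nonlinear_divergence_raises():
    A = np.zeros((1, 1, 1))
    term = NonlinearTerm(target=0, source=0, lag=1, form="square", gain=1.5)
    truth = GroundTruthConnectivity(linear_coeffs=A, nonlinear_terms=(term,))
    with pytest.raises(InstabilityError):
        simulate_nonlinear_mvar(truth, 5000, seed=3)


def test_nonlinear_term_validation():
    with pytest.raises(ValueError):
        NonlinearTerm(target=0, source=1, lag=1, form="cubic", gain=0.1)
    with pytest.raises(ValueError):
        NonlinearTerm(target=0, source=1, lag=1, form="product", gain=0.1)


# ---------------------------------------------------------------------------
# Beta oscillators
# ---------------------------------------------------------------------------

def test_beta_oscillator_unit_variance():
    truth = beta_oscillator_truth()
    x = simulate_nonlinear_mvar(truth, 30000, seed=4)
    # the uncoupled cingulate source is normalized to ~unit SD; the lingual
    # source gains extra variance from the resonantly re-amplified coupling
    assert abs(x[1].std() - 1.0) < 0.1
    assert 0.9 < x[0].std() < 1.7


def test_beta_oscillator_peak_frequency():
    from scipy.signal import welch

    truth = beta_oscillator_truth(fs=300.0, f0=20.0)
    x = simulate_nonlinear_mvar(truth, 30000, seed=5)
    f, pxx = welch(x[0], fs=300.0, nperseg=1024)
    assert abs(f[np.argmax(pxx)] - 20.0) < 2.0


def test_beta_oscillator_stable_with_nonlinear_gain():
    truth = beta_oscillator_truth(nonlinear_gain=0.3)
    x = simulate_nonlinear_mvar(truth, 20000, seed=6)
    assert np.all(np.isfinite(x))


# ---------------------------------------------------------------------------
# Sensor projection
# ---------------------------------------------------------------------------

def test_boundary_envelope():
    env = boundary_envelope(3000, 300.0, [5.0], factor=0.7, halfwidth=0.5)
    assert env[int(5.0 * 300)] == 0.7
    assert env[int(4.0 * 300)] == 1.0
    assert np.all(boundary_envelope(1000, 300.0, [2.0], factor=1.0) == 1.0)


def test_project_sources_snr(sensor_small):
    rng = np.random.default_rng(0)
    sources = rng.standard_normal((2, 4000))
    voxels = [10, 60]
    orients = [np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])]
    clean = project_sources(sensor_small, sources, voxels, orients, snr=0.0)
    noisy = project_sources(sensor_small, sources, voxels, orients, snr=5.0,
                            rng=1)
    resid_rms = np.sqrt(np.mean((noisy - clean) ** 2))
    per_source_rms = np.sqrt(np.mean(sources ** 2, axis=1)).mean()
    assert abs(resid_rms - per_source_rms / 5.0) / (per_source_rms / 5.0) < 0.05
    # unit-RMS gain normalization: each source contributes ~ equal sensor power
    one = project_sources(sensor_small, sources[:1], voxels[:1], orients[:1],
                          snr=0.0)
    other = project_sources(sensor_small, sources[1:], voxels[1:], orients[1:],
                            snr=0.0)
    r = np.sqrt(np.mean(one ** 2)) / np.sqrt(np.mean(other ** 2))
    assert 0.8 < r < 1.25


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def test_cohort_determinism():
    cfg = CohortConfig(n_subjects=3, n_intervals=50, n_eeg_intervals=20)
    a = generate_cohort(cfg, seed=9)
    b = generate_cohort(cfg, seed=9)
    for sa, sb in zip(a.subjects, b.subjects):
        assert np.array_equal(sa.responses, sb.responses)
        assert np.array_equal(sa.eeg, sb.eeg)
        assert sa.profile == sb.profile


def test_cohort_planted_slope_structure():
    cfg = CohortConfig(n_subjects=30, n_intervals=10, gamma=0.0,
                       slope_noise_sd=0.0)
    cohort = generate_cohort(cfg, seed=10)
    assert np.allclose(cohort.true_slopes, 0.30)

    cfg = CohortConfig(n_subjects=60, n_intervals=10, gamma=-0.346,
                       slope_noise_sd=0.0)
    cohort = generate_cohort(cfg, seed=11)
    ages, ncs, slopes = cohort.ages, cohort.nc_values, cohort.true_slopes
    assert np.allclose(slopes, 0.30 - 0.346 * (ages - 13.0) * ncs, atol=1e-12)


def test_cohort_nc_nonnegative():
    cohort = generate_cohort(CohortConfig(n_subjects=40, n_intervals=10),
                             seed=12)
    assert np.all(cohort.nc_values >= 0)


def test_cohort_no_eeg_by_default():
    cohort = generate_cohort(CohortConfig(n_subjects=3, n_intervals=20), seed=0)
    assert cohort.sensor_model is None
    assert all(s.eeg is None for s in cohort.subjects)


def test_cohort_eeg_shapes(eeg_cohort):
    cfg = eeg_cohort.config
    n_samp = int(cfg.n_eeg_intervals * 2.0 * cfg.fs)
    for rec in eeg_cohort.subjects:
        assert rec.eeg.shape == (cfg.n_channels, n_samp)
        assert np.all(np.isfinite(rec.eeg))
    assert eeg_cohort.sensor_model.n_channels == cfg.n_channels
    assert len(eeg_cohort.source_voxels) == 2
    labels = eeg_cohort.sensor_model.atlas_labels
    assert tuple(labels[v] for v in eeg_cohort.source_voxels) == (0, 5)


def test_boundary_power_modulation(eeg_cohort):
    """Beta-band sensor variance drops inside the boundary windows."""
    from segconn import markers

    rec = eeg_cohort.subjects[0]
    fs = eeg_cohort.config.fs
    duration = rec.eeg.shape[1] / fs
    times = rec.response_times[(rec.response_times > 1.0)
                               & (rec.response_times < duration - 1.0)]
    assert times.size > 0
    env = boundary_envelope(rec.eeg.shape[1], fs, times, factor=0.7,
                            halfwidth=0.5)
    inside = rec.eeg[:, env < 1.0].var()
    outside = rec.eeg[:, env == 1.0].var()
    assert inside < outside


def test_save_cohort_roundtrip_files(tmp_path):
    import h5py

    cfg = CohortConfig(n_subjects=2, n_intervals=30, n_eeg_intervals=10)
    cohort = generate_cohort(cfg, seed=13)
    synthdata.save_cohort(cohort, tmp_path)
    subdir = tmp_path / cohort.subjects[0].profile.subject_id
    assert (subdir / "events.tsv").exists()
    assert (subdir / "responses.tsv").exists()
    with h5py.File(subdir / "eeg.h5", "r") as f:
        data = f["eeg"][()]
        assert data.shape[0] == cfg.n_channels
        assert f["eeg"].attrs["fs"] == cfg.fs
    assert np.allclose(data, cohort.subjects[0].eeg.astype(np.float32))
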