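"""Synthetic cohorts for the event-segmentation EEG analysis.

Generates everything the downstream stages consume, with known ground truth:

* a movie "situational change" coding — one count per 2-s interval, drawn from
  the empirical category distribution of the stimulus film;
* per-subject key-press responses following a logistic law in the number of
  changes, with a subject random intercept;
* multichannel EEG obtained by projecting a small set of band-limited sources,
  whose dynamics follow a nonlinear multivariate autoregressive (MVAR) model,
  through a smooth synthetic leadfield, with a multiplicative power decrease
  locked to each response (the boundary-locked modulation);
* ages in 10–16 years and a planted age x connectivity interaction on the
  behavioral responsiveness to situational changes.

Everything is deterministic given ``(config, seed)``: one master seed is
spawned into per-subject and per-stage child streams.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from ._utils import as_rng, check_probability_vector

__all__ = [
    "MovieCoding",
    "SubjectProfile",
    "NonlinearTerm",
    "GroundTruthConnectivity",
    "SensorModel",
    "SubjectRecord",
    "Cohort",
    "CohortConfig",
    "InstabilityError",
    "DEFAULT_CHANGE_COUNTS",
    "default_change_distribution",
    "generate_movie_coding",
    "generate_responses",
    "simulate_nonlinear_mvar",
    "beta_oscillator_truth",
    "make_sensor_model",
    "generate_cohort",
    "save_cohort",
]

#: Interval-category counts of the stimulus film: number of 2-s intervals
#: containing 0, 1, 2, 3, 4 and 5+ situational changes (978 intervals total).
DEFAULT_CHANGE_COUNTS = np.array([512, 276, 104, 46, 30, 10])


def default_change_distribution():
    """Empirical distribution of situational-change counts per 2-s interval."""
    return DEFAULT_CHANGE_COUNTS / DEFAULT_CHANGE_COUNTS.sum()


class InstabilityError(RuntimeError):
    """Raised when a simulated MVAR trajectory diverges."""


@dataclass(frozen=True)
class MovieCoding:
    """Situational-change counts on a timeline of fixed 2-s intervals.

    Interval ``k`` covers the half-open window ``[2k, 2k+2)`` seconds from the
    start of the timeline.
    """

    change_counts: np.ndarray
    interval_duration: float = 2.0

    def __post_init__(self):
        counts = np.asarray(self.change_counts, dtype=int)
        if counts.ndim != 1 or counts.size < 1:
            raise ValueError("change_counts must be a non-empty 1-d sequence")
        if np.any(counts < 0):
            raise ValueError("change counts must be non-negative")
        object.__setattr__(self, "change_counts", counts)

    @property
    def n_intervals(self) -> int:
        return int(self.change_counts.size)

    @property
    def duration(self) -> float:
        return self.n_intervals * self.interval_duration

    def interval_of(self, t: float) -> int:
        return int(np.floor(t / self.interval_duration))


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject behavioral ground truth.

    ``true_slope`` is the subject's responsiveness to situational changes in
    logit units per change; ``nc_cing_to_ling`` is the planted nonlinear
    connectivity (cingulate/SMA -> lingual) that the age moderation acts on.
    """

    subject_id: str
    age: float
    random_intercept: float = 0.0
    true_slope: float = 0.30
    nc_cing_to_ling: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.true_slope):
            raise ValueError("true_slope must be finite")


@dataclass(frozen=True)
class NonlinearTerm:
    """One nonlinear coupling term targeting region ``target``.

    ``form`` is one of ``"square"`` (gain * x_s(n-lag)^2), ``"product"``
    (gain * x_s(n-lag) * x_s2(n-lag2)) or ``"tanh"`` (gain * tanh(x_s(n-lag))).
    """

    target: int
    source: int
    lag: int
    form: str
    gain: float
    source2: int | None = None
    lag2: int | None = None

    def __post_init__(self):
        if self.form not in ("square", "product", "tanh"):
            raise ValueError(f"unknown nonlinear form {self.form!r}")
        if not np.isfinite(self.gain):
            raise ValueError("nonlinear gain must be finite")
        if self.form == "product" and (self.source2 is None or self.lag2 is None):
            raise ValueError("product terms need source2 and lag2")


@dataclass(frozen=True)
class GroundTruthConnectivity:
    """Nonlinear MVAR generative model: x(n) = f(x_p) + noise.

    ``linear_coeffs[j, i, l]`` is the linear coefficient from source region
    ``i`` at lag ``l+1`` onto target region ``j``.
    """

    linear_coeffs: np.ndarray
    nonlinear_terms: tuple = ()
    noise_sd: np.ndarray | float = 1.0

    def __post_init__(self):
        A = np.asarray(self.linear_coeffs, dtype=float)
        if A.ndim != 3 or A.shape[0] != A.shape[1]:
            raise ValueError("linear_coeffs must have shape (M, M, p)")
        object.__setattr__(self, "linear_coeffs", A)
        sd = np.broadcast_to(np.asarray(self.noise_sd, dtype=float), (A.shape[0],)).copy()
        if np.any(sd <= 0):
            raise ValueError("noise_sd must be positive")
        object.__setattr__(self, "noise_sd", sd)
        if self.spectral_radius() >= 1.0:
            raise ValueError(
                f"linear MVAR is unstable (companion spectral radius "
                f"{self.spectral_radius():.4f} >= 1)"
            )

    @property
    def n_regions(self) -> int:
        return self.linear_coeffs.shape[0]

    @property
    def order(self) -> int:
        return self.linear_coeffs.shape[2]

    def companion(self) -> np.ndarray:
        M, _, p = self.linear_coeffs.shape
        C = np.zeros((M * p, M * p))
        for lag in range(p):
            C[:M, lag * M:(lag + 1) * M] = self.linear_coeffs[:, :, lag]
        if p > 1:
            C[M:, :-M] = np.eye(M * (p - 1))
        return C

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.companion()))))


@dataclass(frozen=True)
class SensorModel:
    """Synthetic sensor array, source grid and leadfield.

    The leadfield maps a dipole at voxel ``v`` with moment ``m`` (3-vector) to
    channel amplitudes ``leadfield[:, v, :] @ m``. It is smooth both across
    sensors and across neighboring voxels, so that a focal source produces a
    compact hotspot in beamformer maps.
    """

    positions: np.ndarray          # (C, 3) sensor coordinates
    adjacency: np.ndarray          # (C, C) boolean
    leadfield: np.ndarray          # (C, V, 3)
    grid: np.ndarray               # (V, 3) voxel centers
    edge_length: float
    atlas_labels: np.ndarray       # (V,) region id per voxel

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.grid.shape[0]


# ---------------------------------------------------------------------------
# Movie coding and behavior
# ---------------------------------------------------------------------------

def generate_movie_coding(n_intervals=978, distribution=None, seed=None) -> MovieCoding:
    """Draw i.i.d. situational-change counts for a synthetic movie timeline.

    The default distribution is the empirical category distribution of the
    stimulus film over counts 0..5 (with 5 standing for "5 or more").
    """
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    if distribution is None:
        distribution = default_change_distribution()
    p = check_probability_vector(distribution)
    rng = as_rng(seed)
    counts = rng.choice(p.size, size=int(n_intervals), p=p)
    return MovieCoding(change_counts=counts)


def generate_responses(coding: MovieCoding, profile: SubjectProfile, seed=None):
    """Simulate key presses: one Bernoulli draw per 2-s interval.

    P(response in interval k) = logistic(b0 + u_i + slope_i * changes_k) with
    ``b0 + u_i = random_intercept`` folded into the profile. When an interval
    responds, the key-press time is uniform within the interval.

    Returns
    -------
    responses : (n_intervals,) int array of 0/1
    times : sorted array of absolute response times in seconds
    """
    rng = as_rng(seed)
    eta = profile.random_intercept + profile.true_slope * coding.change_counts
    prob = 1.0 / (1.0 + np.exp(-eta))
    responses = (rng.random(coding.n_intervals) < prob).astype(int)
    hit = np.flatnonzero(responses)
    offsets = rng.uniform(0.0, coding.interval_duration, size=hit.size)
    times = np.sort(hit * coding.interval_duration + offsets)
    return responses, times


# ---------------------------------------------------------------------------
# Nonlinear MVAR source dynamics
# ---------------------------------------------------------------------------

def _nonlinear_drive(term: NonlinearTerm, x: np.ndarray, n: int) -> float:
    xs = x[term.source, n - term.lag]
    if term.form == "square":
        return term.gain * xs * xs
    if term.form == "tanh":
        return term.gain * np.tanh(xs)
    return term.gain * xs * x[term.source2, n - term.lag2]


def simulate_nonlinear_mvar(truth: GroundTruthConnectivity, n_samples, seed=None,
                            zscore=False, burn_in=None):
    """Simulate M source time series from a nonlinear MVAR model.

    A burn-in of at least ``10 * order`` samples is simulated and discarded.
    Divergence (any |x| > 1e6) raises :class:`InstabilityError` naming the
    generative model.
    """
    M, p = truth.n_regions, truth.order
    n_samples = int(n_samples)
    if n_samples <= 10 * p:
        raise ValueError("n_samples must exceed 10 * order")
    burn = int(burn_in) if burn_in is not None else max(10 * p, 200)
    rng = as_rng(seed)
    total = n_samples + burn + p
    x = np.zeros((M, total))
    noise = rng.normal(0.0, 1.0, size=(M, total)) * truth.noise_sd[:, None]
    A = truth.linear_coeffs
    max_lag = max([p] + [t.lag for t in truth.nonlinear_terms]
                  + [t.lag2 for t in truth.nonlinear_terms if t.lag2 is not None])
    for n in range(max_lag, total):
        val = noise[:, n].copy()
        for lag in range(p):
            val += A[:, :, lag] @ x[:, n - lag - 1]
        for term in truth.nonlinear_terms:
            val[term.target] += _nonlinear_drive(term, x, n)
        x[:, n] = val
        if np.any(np.abs(val) > 1e6):
            raise InstabilityError(
                f"MVAR trajectory diverged at sample {n} "
                f"(M={M}, p={p}, {len(truth.nonlinear_terms)} nonlinear terms)"
            )
    out = x[:, p + burn:]
    if zscore:
        out = (out - out.mean(axis=1, keepdims=True)) / out.std(axis=1, keepdims=True)
    return out


def beta_oscillator_truth(nonlinear_gain=0.0, fs=300.0, f0=20.0, r=0.95,
                          cross_coupling=0.05, noise_sd=1.0) -> GroundTruthConnectivity:
    """Two coupled beta-band oscillators with an optional quadratic term.

    Region 0 stands for the lingual/calcarine cluster, region 1 for the
    cingulate/SMA cluster. Each region is an AR(2) resonator at ``f0`` Hz
    (pole radius ``r``), with a weak linear cingulate->lingual coupling at
    lag 1 and, when ``nonlinear_gain != 0``, a quadratic drive in the same
    direction: x_0 += gain * x_1(n-1)^2. ``noise_sd`` is the
    approximate stationary SD of each source (the innovation is rescaled by
    the resonator's variance gain), so nonlinear gains are on a unit scale.
    The coupled region 0 ends up somewhat above unit SD because the incoming
    beta-band drive is re-amplified by its own resonance.
    """
    theta = 2.0 * np.pi * f0 / fs
    a1, a2 = 2.0 * r * np.cos(theta), -r * r
    # innovation scaled so each resonator has ~unit stationary SD: the AR(2)
    # variance gain is (1-a2) / ((1+a2) ((1-a2)^2 - a1^2))
    var_gain = (1.0 - a2) / ((1.0 + a2) * ((1.0 - a2) ** 2 - a1 ** 2))
    noise_sd = noise_sd / np.sqrt(var_gain)
    A = np.zeros((2, 2, 2))
    A[0, 0, 0] = A[1, 1, 0] = a1
    A[0, 0, 1] = A[1, 1, 1] = a2
    # coupling runs cingulate -> lingual only: with no return path, the
    # quadratic drive cannot close a superlinear feedback loop, so the system
    # is stable for any bounded nonlinear gain
    A[0, 1, 0] = cross_coupling
    terms = ()
    if nonlinear_gain != 0.0:
        terms = (NonlinearTerm(target=0, source=1, lag=1, form="square",
                               gain=float(nonlinear_gain)),)
    return GroundTruthConnectivity(linear_coeffs=A, nonlinear_terms=terms,
                                   noise_sd=noise_sd)


# ---------------------------------------------------------------------------
# Sensor model and leadfield
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n, radius):
    i = np.arange(n)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(1.0 - z * z)
    phi = golden * i
    pts = np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)
    return radius * pts


def make_sensor_model(n_channels=60, grid_shape=8, edge_length=0.5,
                      sensor_radius=2.4, n_neighbors=6, cond_cap=1e4,
                      perturbation=0.05, seed=None) -> SensorModel:
    """Build the synthetic sensor array, grid, atlas and leadfield.

    Sensors lie on a sphere; the grid is ``grid_shape**3`` cubic voxels of
    ``edge_length`` units, restricted to a ball inside the sensor sphere, and
    partitioned into 6 "atlas" regions by merging octants. The leadfield is a
    point-dipole potential in an unbounded homogeneous medium plus a small
    spatially smoothed random perturbation; its singular values are clipped so
    the condition number never exceeds ``cond_cap``.
    """
    rng = as_rng(seed)
    positions = _fibonacci_sphere(n_channels, sensor_radius)

    # channel adjacency: mutual k-nearest-neighbour graph, symmetrized
    d = np.linalg.norm(positions[:, None] - positions[None, :], axis=2)
    np.fill_diagonal(d, np.inf)
    adjacency = np.zeros((n_channels, n_channels), dtype=bool)
    for c in range(n_channels):
        adjacency[c, np.argsort(d[c])[:n_neighbors]] = True
    adjacency |= adjacency.T
    np.fill_diagonal(adjacency, False)

    half = grid_shape * edge_length / 2.0
    centers1d = -half + edge_length * (np.arange(grid_shape) + 0.5)
    gx, gy, gz = np.meshgrid(centers1d, centers1d, centers1d, indexing="ij")
    grid = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    keep = np.linalg.norm(grid, axis=1) <= sensor_radius * 0.8
    grid = grid[keep]
    n_voxels = grid.shape[0]

    # 6 atlas regions: octants with the two +z pairs merged
    octant = ((grid[:, 0] > 0).astype(int) + 2 * (grid[:, 1] > 0).astype(int)
              + 4 * (grid[:, 2] > 0).astype(int))
    octant_to_region = np.array([0, 1, 2, 3, 4, 4, 5, 5])
    atlas_labels = octant_to_region[octant]

    # dipole-potential leadfield, smooth in sensor and voxel position
    diff = positions[:, None, :] - grid[None, :, :]          # (C, V, 3)
    dist3 = np.linalg.norm(diff, axis=2) ** 3                # (C, V)
    leadfield = diff / dist3[:, :, None]

    # smoothed random perturbation across the sensor sphere
    sigma = sensor_radius * 0.5
    kernel = np.exp(-(np.linalg.norm(
        positions[:, None] - positions[None, :], axis=2) ** 2) / (2 * sigma ** 2))
    noise = rng.normal(size=(n_channels, n_voxels, 3))
    smooth_noise = np.einsum("cd,dvk->cvk", kernel / kernel.sum(1, keepdims=True), noise)
    scale = np.abs(leadfield).mean()
    leadfield = leadfield + perturbation * scale / np.abs(smooth_noise).mean() * smooth_noise

    # condition-number cap on the flattened (C, 3V) gain matrix
    flat = leadfield.reshape(n_channels, -1)
    U, s, Vt = np.linalg.svd(flat, full_matrices=False)
    s = np.maximum(s, s[0] / cond_cap)
    leadfield = (U @ np.diag(s) @ Vt).reshape(n_channels, n_voxels, 3)

    return SensorModel(positions=positions, adjacency=adjacency,
                       leadfield=leadfield, grid=grid,
                       edge_length=edge_length, atlas_labels=atlas_labels)


def source_patch_gain(sensor: SensorModel, center_voxel, orientation,
                      patch_radius_edges=1.5):
    """Channel gain of an extended cortical patch source.

    The patch covers voxels within ``patch_radius_edges`` grid edges of the
    center, with Gaussian weights (SD = one edge), all sharing one
    orientation — a focal region of coherent activity rather than a point
    dipole, so beamformer maps show a multi-voxel hotspot.
    """
    o = np.asarray(orientation, dtype=float)
    o = o / np.linalg.norm(o)
    d = np.linalg.norm(sensor.grid - sensor.grid[center_voxel], axis=1)
    members = np.flatnonzero(d <= patch_radius_edges * sensor.edge_length)
    w = np.exp(-(d[members] / sensor.edge_length) ** 2 / 2.0)
    w = w / w.sum()
    return np.einsum("cvk,v,k->c", sensor.leadfield[:, members, :], w, o)


def project_sources(sensor: SensorModel, sources: np.ndarray, voxels, orientations,
                    snr=5.0, rng=None, patch_radius_edges=1.5):
    """Project source time series through the leadfield and add sensor noise.

    Each source is an extended patch (see :func:`source_patch_gain`) centered
    on its voxel. Every patch gain pattern is normalized to unit sensor RMS so
    deep and superficial sources contribute equally at the sensors; ``snr`` is
    then the ratio of each (unit-variance) source's sensor RMS to the RMS of
    the additive white sensor noise.
    """
    rng = as_rng(rng)
    C = sensor.n_channels
    eeg = np.zeros((C, sources.shape[1]))
    for k, (v, o) in enumerate(zip(voxels, orientations)):
        gain = source_patch_gain(sensor, v, o, patch_radius_edges)
        gain = gain / (np.linalg.norm(gain) / np.sqrt(C))
        eeg += gain[:, None] * sources[k][None, :]
    per_source_rms = np.sqrt(np.mean(np.asarray(sources) ** 2, axis=1))
    noise_sd = float(per_source_rms.mean()) / snr if snr > 0 else 0.0
    if noise_sd > 0:
        eeg = eeg + rng.normal(0.0, noise_sd, size=eeg.shape)
    return eeg


def boundary_envelope(n_samples, fs, response_times, factor=0.7, halfwidth=0.5):
    """Multiplicative amplitude envelope dipping to ``factor`` around responses."""
    env = np.ones(n_samples)
    for t in np.atleast_1d(response_times):
        lo = max(0, int(np.floor((t - halfwidth) * fs)))
        hi = min(n_samples, int(np.ceil((t + halfwidth) * fs)))
        env[lo:hi] = factor
    return env


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    The behavioral defaults follow the cohort the analysis models: ages
    uniform on 10–16 years, a mixed-logistic response law with fixed intercept
    -3.36 and mean slope 0.30 per situational change, and a planted moderation
    ``slope_i = b1 + gamma * (age_i - mean age) * nc_i + e_i`` with
    ``gamma = -0.346`` acting on per-subject nonlinear connectivity values
    ``nc_i = |Normal(nc_mean, nc_sd)|``. The half-normal draw keeps the
    ground truth in the same nonnegative metric as the estimated quantity
    (a log variance ratio), so estimated and true values are comparable.
    """

    n_subjects: int = 72
    n_intervals: int = 978
    age_range: tuple = (10.0, 16.0)
    intercept: float = -3.36
    slope: float = 0.30
    random_intercept_sd: float = 0.5
    gamma: float = -0.346
    slope_noise_sd: float = 0.05
    nc_mean: float = 0.0
    nc_sd: float = 0.2
    # EEG block (None disables EEG simulation)
    n_eeg_intervals: int | None = None
    fs: float = 300.0
    n_channels: int = 60
    snr: float = 5.0
    boundary_factor: float = 0.7
    boundary_halfwidth: float = 0.5
    nonlinear_gain_scale: float = 0.3   # per-subject gain = scale * nc_i
    source_regions: tuple = (0, 5)      # atlas regions hosting the two sources

    def to_dict(self):
        return dataclasses.asdict(self)


@dataclass
class SubjectRecord:
    profile: SubjectProfile
    coding: MovieCoding
    responses: np.ndarray
    response_times: np.ndarray
    eeg: np.ndarray | None = None
    sources: np.ndarray | None = None
    truth: GroundTruthConnectivity | None = None


@dataclass
class Cohort:
    config: CohortConfig
    subjects: list
    sensor_model: SensorModel | None = None
    source_voxels: tuple | None = None

    @property
    def ages(self):
        return np.array([s.profile.age for s in self.subjects])

    @property
    def nc_values(self):
        return np.array([s.profile.nc_cing_to_ling for s in self.subjects])

    @property
    def true_slopes(self):
        return np.array([s.profile.true_slope for s in self.subjects])


def _pick_source_voxels(sensor: SensorModel, regions):
    """Deterministic source placement: most interior voxel of each region.

    The centroid-closest voxel keeps the source patch away from the grid
    boundary, where the leadfield varies too quickly for an extended patch to
    look dipolar.
    """
    voxels = []
    for r in regions:
        idx = np.flatnonzero(sensor.atlas_labels == r)
        centroid = sensor.grid[idx].mean(axis=0)
        voxels.append(int(idx[np.argmin(
            np.linalg.norm(sensor.grid[idx] - centroid, axis=1))]))
    return tuple(voxels)


def generate_cohort(config: CohortConfig, seed=None) -> Cohort:
    """Generate a complete cohort: profiles, codings, responses, and EEG.

    Sources follow :func:`beta_oscillator_truth` with the quadratic
    cingulate->lingual gain set per subject to
    ``nonlinear_gain_scale * nc_i``; the beta-band source amplitude is
    multiplicatively reduced around each response time (boundary-locked
    decrease) before projection through the leadfield.
    """
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    sensor_ss, *subject_ss = ss.spawn(config.n_subjects + 1)

    sensor = None
    source_voxels = None
    orientations = None
    if config.n_eeg_intervals is not None:
        sensor = make_sensor_model(n_channels=config.n_channels,
                                   seed=np.random.default_rng(sensor_ss))
        source_voxels = _pick_source_voxels(sensor, config.source_regions)
        orientations = (np.array([1.0, 0.3, 0.2]), np.array([0.2, 1.0, -0.3]))

    age_lo, age_hi = config.age_range
    mean_age = 0.5 * (age_lo + age_hi)

    subjects = []
    for i, child in enumerate(subject_ss):
        rng = np.random.default_rng(child)
        age = rng.uniform(age_lo, age_hi)
        nc = abs(rng.normal(config.nc_mean, config.nc_sd))
        u = rng.normal(0.0, config.random_intercept_sd)
        slope = (config.slope + config.gamma * (age - mean_age) * nc
                 + rng.normal(0.0, config.slope_noise_sd))
        profile = SubjectProfile(subject_id=f"sub-{i + 1:03d}", age=age,
                                 random_intercept=config.intercept + u,
                                 true_slope=slope, nc_cing_to_ling=nc)
        coding = generate_movie_coding(config.n_intervals, seed=rng)
        responses, times = generate_responses(coding, profile, seed=rng)

        eeg = sources = truth = None
        if config.n_eeg_intervals is not None:
            n_samp = int(round(config.n_eeg_intervals * coding.interval_duration
                               * config.fs))
            truth = beta_oscillator_truth(
                nonlinear_gain=config.nonlinear_gain_scale * nc, fs=config.fs)
            sources = simulate_nonlinear_mvar(truth, n_samp, seed=rng, zscore=True)
            eeg_times = times[times < config.n_eeg_intervals * coding.interval_duration]
            env = boundary_envelope(n_samp, config.fs, eeg_times,
                                    factor=config.boundary_factor,
                                    halfwidth=config.boundary_halfwidth)
            eeg = project_sources(sensor, sources * env[None, :], source_voxels,
                                  orientations, snr=config.snr, rng=rng)
        subjects.append(SubjectRecord(profile=profile, coding=coding,
                                      responses=responses, response_times=times,
                                      eeg=eeg, sources=sources, truth=truth))
    return Cohort(config=config, subjects=subjects, sensor_model=sensor,
                  source_voxels=source_voxels)


# ---------------------------------------------------------------------------
# Persistence: one directory per subject
# ---------------------------------------------------------------------------

def save_cohort(cohort: Cohort, path):
    """Persist a cohort: per-subject TSV/HDF5 files plus shared sensor files."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    (root / "config.json").write_text(json.dumps(cohort.config.to_dict(), indent=2))
    if cohort.sensor_model is not None:
        sm = cohort.sensor_model
        with open(root / "sensors.sfp", "w") as f:
            for c, (x, y, z) in enumerate(sm.positions):
                f.write(f"ch{c + 1:02d}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")
        with open(root / "adjacency.tsv", "w") as f:
            f.write("ch_a\tch_b\n")
            for a, b in zip(*np.nonzero(np.triu(sm.adjacency))):
                f.write(f"{a}\t{b}\n")
    for rec in cohort.subjects:
        sub = root / rec.profile.subject_id
        sub.mkdir(exist_ok=True)
        with open(sub / "events.tsv", "w") as f:
            f.write("onset_s\ttype\tvalue\n")
            for k, n in enumerate(rec.coding.change_counts):
                f.write(f"{k * rec.coding.interval_duration:.1f}\tchanges\t{n}\n")
        with open(sub / "responses.tsv", "w") as f:
            f.write("onset_s\ttype\n")
            for t in rec.response_times:
                f.write(f"{t:.4f}\tresponse\n")
        meta = {"subject_id": rec.profile.subject_id, "age": rec.profile.age,
                "random_intercept": rec.profile.random_intercept,
                "true_slope": rec.profile.true_slope,
                "nc_cing_to_ling": rec.profile.nc_cing_to_ling}
        if rec.truth is not None:
            meta["ground_truth"] = {
                "linear_coeffs": rec.truth.linear_coeffs.tolist(),
                "noise_sd": rec.truth.noise_sd.tolist(),
                "nonlinear_terms": [dataclasses.asdict(t) for t in rec.truth.nonlinear_terms],
            }
        (sub / "subject.json").write_text(json.dumps(meta, indent=2))
        if rec.eeg is not None:
            with h5py.File(sub / "eeg.h5", "w") as f:
                d = f.create_dataset("eeg", data=rec.eeg.astype(np.float32))
                d.attrs["fs"] = cohort.config.fs
    return root
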