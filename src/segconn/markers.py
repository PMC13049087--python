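"""Boundary-interval (BI) / no-boundary-interval (NBI) marker construction.

The movie timeline is divided into 2-s bins. Bins containing at least one
key press are Boundary Intervals; the rest are No-Boundary Intervals. Each
valid BI gets a marker at the response time; for every BI one NBI is drawn at
random and receives a virtual marker at the same relative offset within the
bin, so the two conditions are sampled identically in time. Every marker must
survive a validity check: its -2..+2 s window lies inside the recording and
contains no other response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._utils import as_rng

__all__ = [
    "MarkerSet",
    "EpochSet",
    "MatchingFailure",
    "label_bins",
    "discard_close_responses",
    "sample_matched_nbi",
    "extract_epochs",
]

logger = logging.getLogger(__name__)

VALIDITY_HALFWIDTH = 2.0  # seconds checked on each side of a marker


class MatchingFailure(RuntimeError):
    """Raised when no valid NBI can be matched to a BI."""


@dataclass(frozen=True)
class MarkerSet:
    """Paired BI and NBI markers (absolute seconds).

    ``pairing[k]`` links ``bi_markers[k]`` with ``nbi_markers[k]``; paired
    markers share the same within-bin relative offset.
    """

    bi_markers: np.ndarray
    nbi_markers: np.ndarray
    bi_bins: np.ndarray
    nbi_bins: np.ndarray
    relative_offsets: np.ndarray

    def __post_init__(self):
        if not (len(self.bi_markers) == len(self.nbi_markers)
                == len(self.relative_offsets)):
            raise ValueError("BI and NBI marker lists must be paired 1:1")

    def __len__(self):
        return len(self.bi_markers)


@dataclass(frozen=True)
class EpochSet:
    """Fixed-length trials cut around markers: (trials, channels, samples)."""

    epochs: np.ndarray
    window: tuple
    fs: float
    condition: str = ""
    times: np.ndarray = None

    def __post_init__(self):
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (trials, channels, samples)")
        n = self.epochs.shape[2]
        expected = int(round((self.window[1] - self.window[0]) * self.fs)) + 1
        if n != expected:
            raise ValueError(f"epoch length {n} inconsistent with window/fs "
                             f"(expected {expected})")
        if self.times is None:
            object.__setattr__(
                self, "times", self.window[0] + np.arange(n) / self.fs)

    @property
    def n_trials(self):
        return self.epochs.shape[0]


def discard_close_responses(response_times, min_gap=2.0):
    """Greedy left-to-right thinning: drop a response closer than ``min_gap``
    (strictly) to the last kept one."""
    times = np.asarray(response_times, dtype=float)
    if times.size == 0:
        return times
    if np.any(np.diff(times) < 0):
        raise ValueError("response times must be sorted")
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= min_gap:
            kept.append(t)
    return np.array(kept)


def label_bins(coding, response_times):
    """Label each 2-s bin BI/NBI and record the first response time per BI.

    Bin ``k`` covers the half-open window [2k, 2k+2); it is a BI iff at least
    one response time falls inside it.

    Returns
    -------
    labels : (n_intervals,) bool array, True for BI
    bi_times : dict bin index -> first response time inside the bin
    """
    times = np.asarray(response_times, dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("response times must be sorted")
    if times.size and (times[0] < 0 or times[-1] >= coding.duration):
        raise ValueError("response times must lie within the timeline")
    labels = np.zeros(coding.n_intervals, dtype=bool)
    bi_times = {}
    for t in times:
        k = coding.interval_of(t)
        labels[k] = True
        bi_times.setdefault(k, t)   # first-response rule
    return labels, bi_times


def _marker_valid(t, response_times, recording_duration, own_response=None):
    """Validity predicate: +-2 s window inside the recording, no other response."""
    if t - VALIDITY_HALFWIDTH < 0 or t + VALIDITY_HALFWIDTH > recording_duration:
        return False
    times = np.asarray(response_times)
    in_window = times[(times > t - VALIDITY_HALFWIDTH)
                      & (times < t + VALIDITY_HALFWIDTH)]
    if own_response is not None:
        in_window = in_window[in_window != own_response]
    return in_window.size == 0


def sample_matched_nbi(coding, response_times, recording_duration, seed=None,
                       max_retries=1000, bin_duration=None) -> MarkerSet:
    """Pair each valid BI with a randomly drawn NBI carrying a virtual marker.

    NBI bins are sampled without replacement; a draw is valid when the virtual
    marker (same relative offset as the paired BI marker) passes the -2..+2 s
    validity predicates. Invalid draws are re-sampled up to ``max_retries``
    times per BI before a :class:`MatchingFailure` is raised.
    """
    rng = as_rng(seed)
    dt = bin_duration if bin_duration is not None else coding.interval_duration
    labels, bi_times = label_bins(coding, response_times)

    bi_bins, bi_markers, offsets = [], [], []
    for k, t in sorted(bi_times.items()):
        if _marker_valid(t, response_times, recording_duration, own_response=t):
            bi_bins.append(k)
            bi_markers.append(t)
            offsets.append(t - k * dt)

    nbi_candidates = np.array([k for k in np.flatnonzero(~labels)
                               if (k + 1) * dt <= recording_duration], dtype=int)
    available = [int(k) for k in rng.permutation(nbi_candidates)]
    nbi_bins, nbi_markers = [], []
    for k_bi, off in zip(bi_bins, offsets):
        placed = False
        for _ in range(max_retries):
            if not available:
                break
            k = available.pop()
            t = k * dt + off
            if _marker_valid(t, response_times, recording_duration):
                nbi_bins.append(k)
                nbi_markers.append(t)
                placed = True
                break
        if not placed:
            raise MatchingFailure(
                f"could not match an NBI for BI bin {k_bi}: "
                f"{len(bi_bins)} BIs, {len(nbi_candidates)} NBI candidates")
    return MarkerSet(bi_markers=np.array(bi_markers),
                     nbi_markers=np.array(nbi_markers),
                     bi_bins=np.array(bi_bins, dtype=int),
                     nbi_bins=np.array(nbi_bins, dtype=int),
                     relative_offsets=np.array(offsets))


def extract_epochs(eeg, marker_times, window, fs, condition="") -> EpochSet:
    """Cut fixed-length epochs around markers.

    The sample at marker time ``t`` is index ``floor(t * fs)``; a window
    (t0, t1) spans ``round((t1 - t0) * fs) + 1`` samples starting at
    ``floor(t * fs) + round(t0 * fs)``. Markers too close to a recording edge
    are dropped with a warning.
    """
    eeg = np.asarray(eeg)
    t0, t1 = window
    n_len = int(round((t1 - t0) * fs)) + 1
    trials, n_dropped = [], 0
    for t in np.atleast_1d(marker_times):
        start = int(np.floor(t * fs)) + int(round(t0 * fs))
        stop = start + n_len
        if start < 0 or stop > eeg.shape[1]:
            n_dropped += 1
            continue
        trials.append(eeg[:, start:stop])
    if n_dropped:
        logger.warning("extract_epochs: dropped %d marker(s) at recording edge",
                       n_dropped)
    epochs = (np.stack(trials) if trials
              else np.empty((0, eeg.shape[0], n_len)))
    return EpochSet(epochs=epochs, window=(float(t0), float(t1)), fs=float(fs),
                    condition=condition)
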