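"""Morlet time–frequency decomposition and band power summaries.

Power is computed with complex Morlet wavelets (5 cycles by default) over
3–30 Hz. Epochs are zero-padded to the next whole second before the transform
(padding length = ceiling of the trial length in samples divided by the
sampling rate), then cropped back, which sets the effective frequency
resolution without touching the analysis window. Band summaries average over
the canonical bands theta 4–7 Hz, alpha 8–12 Hz, beta 15–30 Hz and a time
window of -1..1 s around the marker; the wider -2..2 s extraction window
exists to keep wavelet edge effects out of that summary window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from mne.time_frequency import tfr_array_morlet

__all__ = ["TFR", "BandDefinition", "THETA", "ALPHA", "BETA",
           "morlet_tfr", "band_average"]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float
    hi: float

    def __post_init__(self):
        if not 0 < self.lo < self.hi:
            raise ValueError("band must satisfy 0 < lo < hi")

    def select(self, freqs):
        freqs = np.asarray(freqs)
        return (freqs >= self.lo) & (freqs <= self.hi)


THETA = BandDefinition("theta", 4.0, 7.0)
ALPHA = BandDefinition("alpha", 8.0, 12.0)
BETA = BandDefinition("beta", 15.0, 30.0)


@dataclass(frozen=True)
class TFR:
    """Wavelet power: (trials, channels, freqs, times)."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    fs: float
    wavelet_width: float = 5.0

    def __post_init__(self):
        if self.power.ndim != 4:
            raise ValueError("power must be (trials, channels, freqs, times)")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


def morlet_tfr(epochs, freqs=None, width=5.0, pad_to=None) -> TFR:
    """Morlet-wavelet power of an :class:`~segconn.markers.EpochSet`.

    Parameters
    ----------
    freqs : array of frequencies in Hz (default 3..30 in 1 Hz steps).
    width : wavelet width in cycles per frequency.
    pad_to : total length in seconds to zero-pad each epoch to before the
        transform (default: next whole second of the epoch length).
    """
    if freqs is None:
        freqs = np.arange(3.0, 31.0)
    freqs = np.asarray(freqs, dtype=float)
    fs = epochs.fs
    data = np.asarray(epochs.epochs, dtype=float)
    n_samples = data.shape[2]
    duration = n_samples / fs

    # a wavelet of `width` cycles must fit in the epoch
    f_min_resolvable = width / duration
    if np.any(freqs < f_min_resolvable):
        raise ValueError(
            f"frequencies below {f_min_resolvable:.2f} Hz cannot be resolved "
            f"in a {duration:.2f} s epoch with a width-{width:g} wavelet")

    if pad_to is None:
        pad_to = float(np.ceil(n_samples / fs))
    n_pad_total = int(round(pad_to * fs))
    if n_pad_total < n_samples:
        raise ValueError("pad_to is shorter than the epoch itself")
    pad = n_pad_total - n_samples
    left = pad // 2
    padded = np.pad(data, ((0, 0), (0, 0), (left, pad - left)))

    power = tfr_array_morlet(padded, sfreq=fs, freqs=freqs, n_cycles=width,
                             output="power", zero_mean=True)
    power = power[:, :, :, left:left + n_samples]
    return TFR(power=power, freqs=freqs, times=np.asarray(epochs.times),
               fs=fs, wavelet_width=width)


def band_average(tfr: TFR, band: BandDefinition, time_window=(-1.0, 1.0)):
    """Mean power over a band's frequency bins and a time window.

    Returns a (trials, channels) matrix.
    """
    fsel = band.select(tfr.freqs)
    tsel = (tfr.times >= time_window[0]) & (tfr.times <= time_window[1])
    if not fsel.any():
        raise ValueError(f"band {band.name} has no frequency bins in the TFR")
    if not tsel.any():
        raise ValueError("time window selects no samples")
    return tfr.power[:, :, fsel][:, :, :, tsel].mean(axis=(2, 3))
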