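"""Morlet-wavelet time-frequency decomposition for event-locked analysis.

The frequency grid for the main analyses runs from 1 to 20 Hz in 0.5 Hz
steps with coefficients every 20 ms.  The number of wavelet cycles adapts to
frequency: for f >= 5 Hz it is half the frequency rounded up, but at least
5; below 5 Hz it shrinks to 2-4 cycles so that the wavelet stays short and
more artifact-free segments remain usable.  The wavelet's temporal width is
sigma_t = n_cycles / (pi * f); over the 12-16 Hz spindle grid this averages
about 0.167 s.

Wavelets are L2-normalised and power enters the analyses only through
ratios and contrasts, so absolute units are immaterial.  Cells whose
wavelet support extends past the epoch edge are marked invalid (NaN) rather
than zero-padded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def adaptive_n_cycles(freq_hz: float) -> float:
    """Cycle rule: max(5, ceil(f/2)) for f >= 5 Hz; 2-4 cycles below."""
    if freq_hz >= 5.0:
        return max(5.0, float(np.ceil(freq_hz / 2.0)))
    if freq_hz <= 2.0:
        return 2.0
    if freq_hz <= 3.5:
        return 3.0
    return 4.0


@dataclass(frozen=True)
class WaveletSpec:
    freqs_hz: np.ndarray
    n_cycles: np.ndarray
    time_step_s: float = 0.020

    @property
    def sigma_t(self) -> np.ndarray:
        """Temporal width of each wavelet in seconds, n_cycles/(pi*f)."""
        return self.n_cycles / (np.pi * self.freqs_hz)

    def half_support_s(self) -> np.ndarray:
        """Half-length of the wavelet in seconds (support of the windowed
        carrier, n_cycles/(2 f)); cells closer than this to an epoch edge
        have incomplete support."""
        return self.n_cycles / (2.0 * self.freqs_hz)


def build_wavelet_spec(freq_range: tuple[float, float] = (1.0, 20.0),
                       step: float = 0.5,
                       time_step_s: float = 0.020) -> WaveletSpec:
    if step <= 0:
        raise ValueError("frequency step must be positive")
    lo, hi = freq_range
    freqs = np.arange(lo, hi + step / 2, step)
    n_cycles = np.array([adaptive_n_cycles(f) for f in freqs])
    return WaveletSpec(freqs_hz=freqs, n_cycles=n_cycles,
                       time_step_s=time_step_s)


def mean_sigma_t(band: tuple[float, float] = (12.0, 16.0),
                 step: float = 0.5) -> float:
    """Mean wavelet temporal resolution over a frequency band (seconds)."""
    spec = build_wavelet_spec(band, step)
    return float(np.mean(spec.sigma_t))


@dataclass
class TFRStack:
    """Per-event complex wavelet coefficients.

    coeffs has shape (n_events, n_channels, n_freqs, n_times); invalid
    edge cells are NaN.  ``lock`` names the 0 s alignment point.
    """

    coeffs: np.ndarray
    time_axis_s: np.ndarray
    freq_axis_hz: np.ndarray
    lock: str = "ripple_peak"

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.coeffs) ** 2

    @property
    def n_events(self) -> int:
        return self.coeffs.shape[0]

    def channel(self, idx: int) -> np.ndarray:
        """(n_events, n_freqs, n_times) coefficients of one channel."""
        return self.coeffs[:, idx]


def extract_epochs(data: np.ndarray, fs: float, centers_s: np.ndarray,
                   half_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Cut (n_events, n_channels, n_times) epochs around time points.

    Events whose window would cross a recording edge are dropped; the
    indices of the surviving events are returned alongside.
    """
    data = np.atleast_2d(data)
    half = int(round(half_s * fs))
    n = data.shape[1]
    keep, segs = [], []
    for i, c_s in enumerate(np.asarray(centers_s, float)):
        c = int(round(c_s * fs))
        if c - half < 0 or c + half + 1 > n:
            continue
        keep.append(i)
        segs.append(data[:, c - half: c + half + 1])
    if not segs:
        return np.empty((0, data.shape[0], 2 * half + 1)), np.array([], int)
    return np.stack(segs), np.asarray(keep, int)


def compute_tfr(epochs: np.ndarray, fs: float, spec: WaveletSpec,
                time_step_s: float | None = None,
                t_start_s: float | None = None,
                lock: str = "ripple_peak") -> TFRStack:
    """Complex Morlet TFR of epoched data.

    Parameters
    ----------
    epochs : ndarray (n_events, n_channels, n_times)
    t_start_s : time of the first sample relative to the lock point
        (default: epochs assumed centred, so -(n_times-1)/(2 fs)).
    """
    from mne.time_frequency import tfr_array_morlet

    epochs = np.asarray(epochs, float)
    if epochs.ndim != 3:
        raise ValueError("epochs must be (n_events, n_channels, n_times)")
    n_times = epochs.shape[2]
    step = time_step_s if time_step_s is not None else spec.time_step_s
    decim = max(int(round(step * fs)), 1)
    if t_start_s is None:
        t_start_s = -(n_times - 1) / (2.0 * fs)

    coeffs = tfr_array_morlet(
        epochs, sfreq=fs, freqs=spec.freqs_hz, n_cycles=spec.n_cycles,
        output="complex", decim=decim, zero_mean=True, verbose="error")
    # L2-normalised wavelets respond to a sinusoid in proportion to
    # sqrt(sigma_t); dividing by it makes tone responses flat across the
    # adaptive cycle rule so that frequency profiles and cross-frequency
    # comparisons are unbiased.
    coeffs /= np.sqrt(spec.sigma_t * fs)[None, None, :, None]
    times = t_start_s + np.arange(n_times)[::decim] / fs
    t_end_s = t_start_s + (n_times - 1) / fs

    # mark cells with incomplete wavelet support invalid
    half_support = spec.half_support_s()
    for j, hs in enumerate(half_support):
        bad = (times < t_start_s + hs) | (times > t_end_s - hs)
        coeffs[:, :, j, bad] = np.nan

    return TFRStack(coeffs=coeffs, time_axis_s=times,
                    freq_axis_hz=spec.freqs_hz.copy(), lock=lock)


def compute_tfr_continuous(data: np.ndarray, fs: float, spec: WaveletSpec,
                           decim: int = 5) -> tuple[np.ndarray, int]:
    """Morlet TFR of a continuous multichannel recording.

    Convolves the whole recording once per (channel, frequency) and
    decimates; event-locked stacks are then cheap slices
    (:func:`slice_continuous_tfr`).  Wavelets have full support everywhere
    except within a wavelet half-length of the recording edges, where
    coefficients are NaN.

    Returns (coeffs, decim) with coeffs complex64 of shape
    (n_channels, n_freqs, ceil(n_samples/decim)); the coefficient at index
    k corresponds to sample k*decim.
    """
    from mne.time_frequency.tfr import morlet
    from scipy.signal import oaconvolve

    data = np.atleast_2d(np.asarray(data, float))
    n_ch, n = data.shape
    Ws = morlet(fs, spec.freqs_hz, n_cycles=spec.n_cycles, zero_mean=True)
    n_dec = int(np.ceil(n / decim))
    out = np.empty((n_ch, len(spec.freqs_hz), n_dec), dtype=np.complex64)
    scale = 1.0 / np.sqrt(spec.sigma_t * fs)
    for fi, W in enumerate(Ws):
        for ci in range(n_ch):
            c = oaconvolve(data[ci], W, mode="same")[::decim]
            c *= scale[fi]
            half = len(W) // 2
            edge = int(np.ceil(half / decim))
            c[:edge] = np.nan
            c[len(c) - edge:] = np.nan
            out[ci, fi] = c.astype(np.complex64)
    return out, decim


def slice_continuous_tfr(coeffs: np.ndarray, decim: int, fs: float,
                         centers_s: np.ndarray, half_s: float,
                         freqs_hz: np.ndarray, step_mult: int = 1,
                         lock: str = "ripple_peak") -> tuple[TFRStack, np.ndarray]:
    """Cut event-locked stacks out of a continuous TFR.

    Lock points are snapped to the decimated grid (error ≤ decim/2
    samples).  ``step_mult`` subsamples the sliced time axis further (e.g.
    4 to go from a 5-sample to a 20-sample coefficient step).  Events whose
    window would leave the valid region are dropped; surviving indices are
    returned.
    """
    n_ch, n_freqs, n_dec = coeffs.shape
    hw = int(round(half_s * fs / decim))
    hw -= hw % step_mult
    keep, segs = [], []
    for i, c_s in enumerate(np.asarray(centers_s, float)):
        ic = int(round(c_s * fs / decim))
        if ic - hw < 0 or ic + hw + 1 > n_dec:
            continue
        keep.append(i)
        segs.append(coeffs[:, :, ic - hw: ic + hw + 1: step_mult])
    if not segs:
        empty = np.empty((0, n_ch, n_freqs, 0), complex)
        return (TFRStack(coeffs=empty, time_axis_s=np.array([]),
                         freq_axis_hz=np.asarray(freqs_hz), lock=lock),
                np.array([], int))
    stack = np.stack(segs).astype(complex)
    times = np.arange(-hw, hw + 1, step_mult) * decim / fs
    return (TFRStack(coeffs=stack, time_axis_s=times,
                     freq_axis_hz=np.asarray(freqs_hz), lock=lock),
            np.asarray(keep, int))


def baseline_percent_change(tfr: TFRStack,
                            window_s: tuple[float, float] = (-2.0, -1.5)
                            ) -> np.ndarray:
    """Power as percentage change from a pre-event baseline window.

    Returns (n_events, n_channels, n_freqs, n_times); per event, channel and
    frequency the baseline is the mean power inside ``window_s``.
    """
    sel = (tfr.time_axis_s >= window_s[0]) & (tfr.time_axis_s <= window_s[1])
    if not sel.any():
        raise ValueError(f"baseline window {window_s} outside the time axis")
    power = tfr.power
    base = np.nanmean(power[..., sel], axis=-1, keepdims=True)
    if np.any(base == 0):
        raise ValueError("zero baseline power")
    return 100.0 * (power - base) / base
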