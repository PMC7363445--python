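"""Detection of discrete sleep spindles and hippocampal sharp-wave ripples.

Both detectors follow the same scheme: band-pass the signal (12–16 Hz for
spindles, 80–120 Hz for ripples), compute a smoothed moving-RMS envelope
(200 ms windows for spindles, 20 ms for ripples), and mark events as maximal
runs where the envelope exceeds a data-derived threshold (mean + 1.25·SD of
the envelope across artifact-free NREM samples for spindles, mean + 2.5·SD
for ripples).  Runs must satisfy duration bounds (0.4–3 s spindles,
38–500 ms ripples); runs whose envelope exceeds an upper guard threshold
(mean + 5·SD / mean + 9·SD) anywhere are discarded as probable artifacts.
Ripples must additionally show at least three cycles in the broadband
signal, and every candidate must pass a frequency-profile check: the
event-locked spectral profile must have a prominent peak (>=20% prominence)
inside the band of interest, which discards broadband transients.

Because thresholds are derived from the data, the detected event set is
invariant under positive rescaling of the input signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .artifacts import ArtifactMask, bandpass, moving_rms, moving_mean, _runs
from .io import make_event_list, empty_event_list

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectorParams:
    band_hz: tuple[float, float]
    rms_window_s: float
    smooth_window_s: float
    thresh_sd: float
    upper_sd: float
    min_dur_s: float
    max_dur_s: float
    min_cycles: int | None
    profile_band_hz: tuple[float, float]
    profile_freqs: tuple[float, float, float]  # start, stop, step (Hz)
    profile_halfwindow_s: float
    profile_avg_halfwindow_s: float
    prominence_frac: float = 0.2
    kind: str = "spindle"

    def __post_init__(self) -> None:
        lo, hi = self.band_hz
        if not lo < hi:
            raise ValueError("band_hz must be (low, high) with low < high")
        if not self.thresh_sd < self.upper_sd:
            raise ValueError("thresh_sd must be below upper_sd")
        if not self.min_dur_s <= self.max_dur_s:
            raise ValueError("min_dur_s must be <= max_dur_s")


SPINDLE_PARAMS = DetectorParams(
    band_hz=(12.0, 16.0),
    rms_window_s=0.2,
    smooth_window_s=0.2,
    thresh_sd=1.25,
    upper_sd=5.0,
    min_dur_s=0.4,
    max_dur_s=3.0,
    min_cycles=None,
    profile_band_hz=(12.0, 16.0),
    profile_freqs=(9.0, 19.0, 0.5),
    profile_halfwindow_s=0.75,
    profile_avg_halfwindow_s=0.5,
    kind="spindle",
)

RIPPLE_PARAMS = DetectorParams(
    band_hz=(80.0, 120.0),
    rms_window_s=0.02,
    smooth_window_s=0.02,
    thresh_sd=2.5,
    upper_sd=9.0,
    min_dur_s=0.038,  # 3 cycles at 80 Hz
    max_dur_s=0.5,
    min_cycles=3,
    profile_band_hz=(80.0, 120.0),
    profile_freqs=(65.0, 135.0, 2.0),
    profile_halfwindow_s=0.1,
    profile_avg_halfwindow_s=0.05,
    kind="ripple",
)


def ripple_min_duration_s(low_hz: float = 80.0, n_cycles: int = 3) -> float:
    """Shortest admissible ripple: ``n_cycles`` at the band's low edge,
    rounded up to the millisecond (3 cycles at 80 Hz -> 0.038 s)."""
    import math

    return math.ceil(n_cycles / low_hz * 1000) / 1000


def rms_envelope(signal: np.ndarray, fs: float, window_s: float,
                 smooth_s: float | None = None) -> np.ndarray:
    """Centred moving RMS followed by a centred moving average of the same
    (or given) window length; same length as the input."""
    if len(signal) == 0:
        raise ValueError("empty signal")
    env = moving_rms(signal, fs, window_s)
    return moving_mean(env, fs, smooth_s if smooth_s is not None else window_s)


def count_raw_cycles(signal: np.ndarray, fs: float,
                     onset_s: float, offset_s: float,
                     band_hz: tuple[float, float] = (40.0, 300.0),
                     amp_frac: float = 0.5,
                     filtered: np.ndarray | None = None) -> int:
    """Oscillatory cycles within [onset, offset] of the broadband trace.

    Operationalises visual cycle counting: extrema with peak prominence of
    at least ``amp_frac`` times the segment's maximum absolute amplitude
    are found on a broadly filtered trace (for ripples, 40–300 Hz — below
    half the ripple band's low edge — which removes the sharp-wave offset
    and 1/f drift that make cycle counting on the raw trace ill-posed),
    and a cycle is a pair of successive alternating extrema.  Small
    background wiggles do not count; the event's own oscillation does.
    """
    from scipy.signal import find_peaks

    x = filtered if filtered is not None else bandpass(
        signal, fs, band_hz[0], band_hz[1], transition_hz=20.0)
    k0, k1 = int(round(onset_s * fs)), int(round(offset_s * fs)) + 1
    seg = x[max(k0, 0): min(k1, len(x))]
    if len(seg) < 3:
        return 0
    amax = np.abs(seg).max()
    if amax <= 0:
        return 0
    prom = amp_frac * amax
    peaks, _ = find_peaks(seg, prominence=prom)
    troughs, _ = find_peaks(-seg, prominence=prom)
    extrema = np.sort(np.concatenate([peaks, troughs]))
    # count alternating peak-trough pairs
    kinds = np.isin(extrema, peaks)
    n_alt = 1 if len(extrema) else 0
    for i in range(1, len(extrema)):
        if kinds[i] != kinds[i - 1]:
            n_alt += 1
    return n_alt // 2


def _event_profiles(signal: np.ndarray, fs: float, peaks_s: np.ndarray,
                    params: DetectorParams) -> tuple[np.ndarray, np.ndarray]:
    """Event-locked frequency profiles (n_events, n_freqs): mean wavelet
    amplitude over ±profile_avg_halfwindow_s around each event peak."""
    from .spectral import build_wavelet_spec, compute_tfr

    start, stop, step = params.profile_freqs
    spec = build_wavelet_spec((start, stop), step)
    # segment must cover the averaging window plus wavelet support
    max_half_support = float(np.max(5.0 * spec.sigma_t))
    half_s = params.profile_halfwindow_s + max_half_support
    half = int(np.ceil(half_s * fs))
    segs = []
    for pk in peaks_s:
        c = int(round(pk * fs))
        if c - half < 0 or c + half + 1 > len(signal):
            segs.append(None)
            continue
        segs.append(signal[c - half: c + half + 1])
    valid = [i for i, s in enumerate(segs) if s is not None]
    profiles = np.full((len(peaks_s), len(spec.freqs_hz)), np.nan)
    if valid:
        epochs = np.stack([segs[i] for i in valid])[:, None, :]
        tfr = compute_tfr(epochs, fs, spec, time_step_s=0.002,
                          t_start_s=-half_s)
        amp = np.abs(tfr.coeffs[:, 0])  # (n_valid, n_freq, n_time)
        sel = np.abs(tfr.time_axis_s) <= params.profile_avg_halfwindow_s + 1e-9
        prof = np.nanmean(amp[:, :, sel], axis=2)
        for j, i in enumerate(valid):
            profiles[i] = prof[j]
    return profiles, spec.freqs_hz


def profile_has_prominent_peak(profile: np.ndarray, freqs: np.ndarray,
                               band_hz: tuple[float, float],
                               prominence_frac: float = 0.2) -> bool:
    """True iff the profile's maximum is a prominent interior peak inside
    ``band_hz``.

    The global maximum must (a) lie strictly inside the grid (a maximum at
    an edge has no decline on both sides), (b) fall inside the band of
    interest, and (c) have peak prominence of at least ``prominence_frac``
    times the profile maximum.  Broadband transients fail because their 1/f
    tilt puts the maximum at the low-frequency edge of the grid.
    """
    from scipy.signal import find_peaks

    if np.any(~np.isfinite(profile)):
        return False
    imax = int(np.argmax(profile))
    if imax == 0 or imax == len(profile) - 1:
        return False
    if not band_hz[0] <= freqs[imax] <= band_hz[1]:
        return False
    peaks, props = find_peaks(profile,
                              prominence=prominence_frac * profile[imax])
    return imax in peaks


def frequency_profile_ok(signal: np.ndarray, fs: float, peak_s: float,
                         params: DetectorParams) -> bool:
    """Single-event convenience wrapper around the batched profile check."""
    profiles, freqs = _event_profiles(signal, fs, np.array([peak_s]), params)
    return profile_has_prominent_peak(profiles[0], freqs,
                                      params.profile_band_hz,
                                      params.prominence_frac)


def detect_events(signal: np.ndarray, fs: float, artifact_mask: ArtifactMask | np.ndarray,
                  nrem: np.ndarray, params: DetectorParams,
                  channel: str = "", check_profile: bool = True) -> pd.DataFrame:
    """Run one detector over a continuous channel.

    ``artifact_mask`` may be an :class:`ArtifactMask` or a boolean array
    (True = artifact).  Returns a validated event table; thresholds are
    computed over artifact-free NREM samples only.
    """
    art = artifact_mask.mask if isinstance(artifact_mask, ArtifactMask) else np.asarray(artifact_mask, bool)
    nrem = np.asarray(nrem, bool)
    if len(art) != len(signal) or len(nrem) != len(signal):
        raise ValueError("masks must be aligned to the signal")
    pool = nrem & ~art
    if not pool.any():
        raise ValueError("no artifact-free NREM samples to derive thresholds")

    lo, hi = params.band_hz
    filt = bandpass(signal, fs, lo, hi, transition_hz=max(1.0, 0.25 * lo))
    env = rms_envelope(filt, fs, params.rms_window_s, params.smooth_window_s)
    mu = env[pool].mean()
    sd = env[pool].std()
    thr = mu + params.thresh_sd * sd
    upper = mu + params.upper_sd * sd

    pad = int(np.ceil(params.profile_halfwindow_s * fs))
    raw_filt = None
    if params.min_cycles:
        raw_filt = bandpass(signal, fs,
                            params.band_hz[0] / 2,
                            min(300.0, 0.999 * fs / 2), transition_hz=20.0)

    candidates = []
    n_rej = dict(duration=0, upper=0, masked=0, cycles=0, profile=0, edge=0)
    for k0, k1 in _runs(env > thr):
        dur = (k1 - k0) / fs
        if dur < params.min_dur_s or dur > params.max_dur_s:
            n_rej["duration"] += 1
            continue
        if (env[k0:k1] > upper).any():
            n_rej["upper"] += 1
            continue
        a, b = max(k0 - pad, 0), min(k1 + pad, len(signal))
        if not pool[a:b].all():
            n_rej["masked"] += 1
            continue
        seg = filt[k0:k1]
        if params.kind == "ripple":
            peak_idx = k0 + int(np.argmax(seg))  # maximum positive peak
        else:
            peak_idx = k0 + int(np.argmin(seg))  # deepest trough
        if params.min_cycles:
            ncyc = count_raw_cycles(signal, fs, k0 / fs, k1 / fs,
                                    filtered=raw_filt)
            if ncyc < params.min_cycles:
                n_rej["cycles"] += 1
                continue
        candidates.append(dict(
            channel=channel, kind=params.kind, onset_s=k0 / fs,
            offset_s=k1 / fs, peak_s=peak_idx / fs, duration_s=dur,
            peak_amp_uv=float(np.abs(seg).max()),
        ))

    if check_profile and candidates:
        peaks = np.array([c["peak_s"] for c in candidates])
        profiles, freqs = _event_profiles(signal, fs, peaks, params)
        kept = []
        for c, prof in zip(candidates, profiles):
            if np.any(~np.isfinite(prof)):
                n_rej["edge"] += 1
                logger.info("event at %.2f s rejected: too close to edge "
                            "for frequency profile", c["peak_s"])
            elif profile_has_prominent_peak(prof, freqs, params.profile_band_hz,
                                            params.prominence_frac):
                kept.append(c)
            else:
                n_rej["profile"] += 1
        candidates = kept

    logger.info("%s detector (%s): %d events kept, rejections: %s",
                params.kind, channel, len(candidates), n_rej)
    if not candidates:
        return empty_event_list()
    for i, c in enumerate(candidates):
        c["id"] = i
    return make_event_list(candidates)


def event_density(events: pd.DataFrame, clean_nrem_duration_s: float) -> float:
    """Events per minute of artifact-free NREM time."""
    if clean_nrem_duration_s <= 0:
        raise ValueError("clean NREM duration must be positive")
    return len(events) / (clean_nrem_duration_s / 60.0)


def match_events(detected: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Score detected vs ground-truth events by any temporal overlap.

    Returns dict with tp/fp/fn counts, precision, recall and F1.
    """
    def _overlaps(a0, a1, b0, b1):
        return (a0 < b1) and (b0 < a1)

    truth_iv = list(zip(truth["onset_s"], truth["offset_s"]))
    det_iv = list(zip(detected["onset_s"], detected["offset_s"]))
    matched_truth = set()
    tp = 0
    for d0, d1 in det_iv:
        hit = None
        for j, (t0, t1) in enumerate(truth_iv):
            if _overlaps(d0, d1, t0, t1):
                hit = j
                break
        if hit is not None:
            tp += 1
            matched_truth.add(hit)
    fp = len(det_iv) - tp
    fn = len(truth_iv) - len(matched_truth)
    precision = tp / max(tp + fp, 1)
    recall = len(matched_truth) / max(len(truth_iv), 1)
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return dict(tp=tp, fp=fp, fn=fn, precision=precision, recall=recall, f1=f1)
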