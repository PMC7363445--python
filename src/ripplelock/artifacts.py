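"""Automated artifact rejection for sleep EEG.

Three detectors run per channel and (where a hypnogram is supplied) with
stage-specific thresholds:

* amplitude — absolute value of the 0.3–150 Hz band-passed signal beyond
  ±750 µV;
* gradient — sample-to-sample difference of the band-passed signal outside
  median ± 6·IQR (catches interictal spikes and step discontinuities);
* hf_burst — RMS (100 ms window) of the >150 Hz high-passed signal above
  median + 4·IQR for at least 100 ms (arousal/movement noise).

Detected samples are padded by ±250 ms, and clean gaps shorter than 3 s
between artifacts are themselves marked artifactual (``short_gap``), so the
surviving clean spans are long enough for event detection and epoching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import Hypnogram

AMPLITUDE_THRESH_UV = 750.0
GRADIENT_IQR_MULT = 6.0
HF_IQR_MULT = 4.0
HF_MIN_RUN_S = 0.1
PAD_S = 0.25
MIN_CLEAN_GAP_S = 3.0

ARTIFACT_CLASSES = ("amplitude", "gradient", "hf_burst", "short_gap")


@dataclass
class ArtifactMask:
    """Per-sample exclusion track with per-class provenance."""

    mask: np.ndarray  # bool, True = artifact
    provenance: dict[str, np.ndarray]  # class -> bool array
    params_used: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cls, m in self.provenance.items():
            if cls not in ARTIFACT_CLASSES:
                raise ValueError(f"unknown artifact class {cls!r}")
            if len(m) != len(self.mask):
                raise ValueError("provenance length mismatch")
        covered = np.zeros_like(self.mask)
        for m in self.provenance.values():
            covered |= m
        if not np.array_equal(covered, self.mask):
            raise ValueError("mask must equal the union of its provenance")

    @property
    def n_samples(self) -> int:
        return len(self.mask)

    def clean(self) -> np.ndarray:
        return ~self.mask

    def intervals(self) -> list[tuple[int, int, str]]:
        """(start, end, classes) half-open sample intervals, classes
        comma-joined."""
        out = []
        for k0, k1 in _runs(self.mask):
            classes = sorted(
                cls for cls, m in self.provenance.items() if m[k0:k1].any()
            )
            out.append((k0, k1, ",".join(classes)))
        return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def _fir_zerophase(signal: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Zero-phase FIR filtering: odd-length linear-phase taps applied in a
    single pass (symmetric taps have zero group delay in 'same' mode); the
    signal is edge-padded by reflection to suppress boundary transients."""
    half = len(taps) // 2
    # odd reflection keeps the derivative continuous at the boundary, so
    # ongoing oscillations do not acquire a kink (and spurious
    # high-frequency edge transients) from the padding
    padded = np.pad(signal, half, mode="reflect", reflect_type="odd")
    return sps.fftconvolve(padded, taps, mode="same")[half:-half]


def bandpass(signal: np.ndarray, fs: float, lo: float, hi: float,
             transition_hz: float | None = None) -> np.ndarray:
    """Zero-phase FIR band-pass (Hamming design, >50 dB stopband).

    The filter length is set from the requested transition width (default:
    the lower band edge, so a 0.3 Hz edge gets a correspondingly long
    filter).
    """
    if hi >= fs / 2:
        hi = 0.999 * fs / 2
    trans = transition_hz if transition_hz is not None else lo
    numtaps = int(min(3.3 * fs / trans, len(signal) - 1)) | 1
    if numtaps < 11:
        raise ValueError("signal too short for the requested filter")
    taps = sps.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs)
    return _fir_zerophase(signal, taps)


def highpass(signal: np.ndarray, fs: float, lo: float,
             transition_hz: float = 10.0) -> np.ndarray:
    numtaps = int(min(3.3 * fs / transition_hz, len(signal) - 1)) | 1
    if numtaps < 11:
        raise ValueError("signal too short for the requested filter")
    taps = sps.firwin(numtaps, lo, pass_zero=False, fs=fs)
    return _fir_zerophase(signal, taps)


def acquisition_style_bandpass(signal: np.ndarray, fs: float,
                               lo: float = 0.3, hi: float = 150.0
                               ) -> np.ndarray:
    """Causal first-order high-pass + zero-phase low-pass.

    Amplitude-based artifact scoring needs the full excursion of a
    sustained deflection: a zero-phase (symmetric) high-pass splits a step
    response in half, so an 800 µV plateau would never reach a ±750 µV
    bound.  A causal first-order high-pass — the shape of a clinical
    acquisition filter — preserves the initial excursion while still
    removing drift.
    """
    b, a = sps.butter(1, lo, btype="highpass", fs=fs)
    x = sps.lfilter(b, a, signal)
    numtaps = int(min(3.3 * fs / 10.0, len(signal) - 1)) | 1
    if numtaps < 11:
        raise ValueError("signal too short for the requested filter")
    taps = sps.firwin(numtaps, hi, pass_zero=True, fs=fs)
    return _fir_zerophase(x, taps)


def moving_rms(signal: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    """Centred moving-window RMS; shrinking windows at the edges."""
    if len(signal) == 0:
        raise ValueError("empty signal")
    w = max(int(round(window_s * fs)), 2)
    sq = signal.astype(float) ** 2
    csum = np.concatenate([[0.0], np.cumsum(sq)])
    half_lo = w // 2
    half_hi = w - half_lo
    idx = np.arange(len(signal))
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi, len(signal))
    return np.sqrt((csum[hi] - csum[lo]) / (hi - lo))


def moving_mean(signal: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    if len(signal) == 0:
        raise ValueError("empty signal")
    w = max(int(round(window_s * fs)), 2)
    csum = np.concatenate([[0.0], np.cumsum(signal.astype(float))])
    half_lo = w // 2
    half_hi = w - half_lo
    idx = np.arange(len(signal))
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi, len(signal))
    return (csum[hi] - csum[lo]) / (hi - lo)


def _stage_groups(stage_vec: np.ndarray | None, n: int) -> list[np.ndarray]:
    """Boolean sample groups over which thresholds are computed separately."""
    if stage_vec is None:
        return [np.ones(n, dtype=bool)]
    groups = []
    for st in np.unique(stage_vec):
        sel = stage_vec == st
        if st == "unscored" or sel.sum() < 100:
            continue
        groups.append(sel)
    covered = np.zeros(n, dtype=bool)
    for g in groups:
        covered |= g
    if (~covered).any():
        groups.append(~covered)  # global threshold for leftover samples
    return groups or [np.ones(n, dtype=bool)]


def detect_amplitude_artifacts(
    signal: np.ndarray, fs: float, *, threshold_uv: float = AMPLITUDE_THRESH_UV,
    filtered: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """Samples of the 0.3–150 Hz filtered trace beyond ±threshold."""
    if fs < 300:
        raise ValueError("fs must be >= 300 Hz for the 0.3-150 Hz band")
    x = (acquisition_style_bandpass(signal, fs) if filtered is None
         else filtered)
    return _runs(np.abs(x) > threshold_uv)


def detect_gradient_artifacts(
    signal: np.ndarray, fs: float, *, iqr_mult: float = GRADIENT_IQR_MULT,
    stage_vec: np.ndarray | None = None, filtered: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """First-difference outliers: diff outside median ± mult·IQR.

    Two-sided by construction.  A constant-derivative signal (IQR = 0) has
    no transient, so a degenerate IQR yields no flags.
    """
    if len(signal) < 2:
        raise ValueError("signal shorter than 2 samples")
    if fs < 300:
        raise ValueError("fs must be >= 300 Hz for the 0.3-150 Hz band")
    x = bandpass(signal, fs, 0.3, 150.0) if filtered is None else filtered
    d = np.diff(x)
    flags = np.zeros(len(signal), dtype=bool)
    for sel in _stage_groups(stage_vec, len(signal)):
        dsel = sel[:-1]
        if dsel.sum() < 4:
            continue
        med = np.median(d[dsel])
        q75, q25 = np.percentile(d[dsel], [75, 25])
        iqr = q75 - q25
        if iqr <= 0:
            continue
        bad = dsel & ((d > med + iqr_mult * iqr) | (d < med - iqr_mult * iqr))
        # flag both samples adjacent to an outlying difference
        flags[:-1] |= bad
        flags[1:] |= bad
    return _runs(flags)


def detect_hf_burst_artifacts(
    signal: np.ndarray, fs: float, *, iqr_mult: float = HF_IQR_MULT,
    min_run_s: float = HF_MIN_RUN_S, stage_vec: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """>150 Hz RMS bursts above median + mult·IQR lasting >= min_run_s.

    The centred 100 ms RMS window smears a burst of duration d into a
    supra-threshold run of roughly d + window, so the run length is
    compensated by the window before the duration rule is applied — a
    strong 50 ms transient must not satisfy the "at least 100 ms"
    criterion merely through smearing.
    """
    if fs <= 300:
        raise ValueError("fs must exceed 300 Hz for a 150 Hz high-pass")
    window_s = 0.1
    hf = highpass(signal, fs, 150.0)
    rms = moving_rms(hf, fs, window_s)
    flags = np.zeros(len(signal), dtype=bool)
    for sel in _stage_groups(stage_vec, len(signal)):
        med = np.median(rms[sel])
        q75, q25 = np.percentile(rms[sel], [75, 25])
        flags |= sel & (rms > med + iqr_mult * (q75 - q25))
    min_run = int(round((min_run_s + window_s) * fs))
    return [(k0, k1) for k0, k1 in _runs(flags) if k1 - k0 >= min_run]


def finalize_mask(
    intervals_per_class: dict[str, list[tuple[int, int]]],
    fs: float,
    n_samples: int,
    *,
    pad_s: float = PAD_S,
    min_clean_gap_s: float = MIN_CLEAN_GAP_S,
    params: dict | None = None,
) -> ArtifactMask:
    """Union per-class intervals, pad ±250 ms, close clean gaps < 3 s."""
    pad = int(round(pad_s * fs))
    provenance = {}
    union = np.zeros(n_samples, dtype=bool)
    for cls, intervals in intervals_per_class.items():
        m = np.zeros(n_samples, dtype=bool)
        for k0, k1 in intervals:
            if not (0 <= k0 <= k1 <= n_samples):
                raise ValueError(f"interval ({k0},{k1}) out of bounds")
            m[max(k0 - pad, 0): min(k1 + pad, n_samples)] = True
        provenance[cls] = m
        union |= m

    short_gap = np.zeros(n_samples, dtype=bool)
    min_gap = int(round(min_clean_gap_s * fs))
    runs = _runs(union)
    for (a0, a1), (b0, b1) in zip(runs[:-1], runs[1:]):
        if b0 - a1 < min_gap:
            short_gap[a1:b0] = True
    union |= short_gap
    if short_gap.any():
        provenance["short_gap"] = short_gap

    return ArtifactMask(
        mask=union,
        provenance=provenance,
        params_used=dict(pad_s=pad_s, min_clean_gap_s=min_clean_gap_s,
                         **(params or {})),
    )


def detect_all(
    signal: np.ndarray,
    fs: float,
    hypnogram: Hypnogram | None = None,
    *,
    amplitude_uv: float = AMPLITUDE_THRESH_UV,
    gradient_iqr: float = GRADIENT_IQR_MULT,
    hf_iqr: float = HF_IQR_MULT,
) -> ArtifactMask:
    """Run all three detectors on one channel and finalize the mask."""
    stage_vec = (hypnogram.stage_vector(fs, len(signal))
                 if hypnogram is not None else None)
    filt = bandpass(signal, fs, 0.3, 150.0)
    per_class = {
        "amplitude": detect_amplitude_artifacts(
            signal, fs, threshold_uv=amplitude_uv),
        "gradient": detect_gradient_artifacts(
            signal, fs, iqr_mult=gradient_iqr, stage_vec=stage_vec,
            filtered=filt),
        "hf_burst": detect_hf_burst_artifacts(
            signal, fs, iqr_mult=hf_iqr, stage_vec=stage_vec),
    }
    return finalize_mask(
        per_class, fs, len(signal),
        params=dict(amplitude_uv=amplitude_uv, gradient_iqr=gradient_iqr,
                    hf_iqr=hf_iqr))


def combine_masks(*masks: ArtifactMask) -> ArtifactMask:
    """Union of per-channel masks (an artifact anywhere excludes the epoch)."""
    n = masks[0].n_samples
    provenance: dict[str, np.ndarray] = {}
    union = np.zeros(n, dtype=bool)
    for m in masks:
        if m.n_samples != n:
            raise ValueError("mask length mismatch")
        union |= m.mask
        for cls, pm in m.provenance.items():
            provenance[cls] = provenance.get(cls, np.zeros(n, bool)) | pm
    params = {}
    for m in masks:
        params.update(m.params_used)
    return ArtifactMask(mask=union, provenance=provenance, params_used=params)
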