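"""Synthetic two-channel sleep-EEG generator with ground truth.

Produces a neocortical ("NC") and a hippocampal ("HIPP") channel containing
1/f background with a slow-oscillation component, embedded 12-16 Hz spindle
bursts, 80-120 Hz ripple bursts riding on ~3 Hz sharp waves, optional
injected artifacts, and a hypnogram.  Cross-regional coupling is
controllable: a configurable fraction of ripples is preceded by spindles in
both channels, and the coupled HIPP spindle-band carrier is a delayed,
scaled copy of the NC carrier, giving a ground-truth NC->HIPP direction for
connectivity analyses.

The generator is a statistical phantom, not a biophysical model: its purpose
is to make every downstream stage testable against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal.windows import hann, tukey

from .io import Recording, Hypnogram, make_event_list, EVENT_COLUMNS


@dataclass
class BackgroundConfig:
    """Ongoing activity underneath the discrete events.

    Besides the 1/f noise and the slow oscillation, the HIPP channel
    carries dense bounded-amplitude sub-ripple high-frequency bursts
    emulating hippocampal gamma/HFO background.  These are load-bearing
    for the data-derived detection thresholds (mean + k*SD of the RMS
    envelope): bounded high-duty activity inflates the pooled SD without
    the Gaussian tails that would cross the detection threshold.
    Optional waxing-and-waning Gaussian band components (sigma- and
    ripple-band) are available but off by default.
    """

    pink_exponent: float = 1.0  # spectral slope of 1/f^a background
    rms_uv: float = 20.0
    so_freq_hz: float = 0.8
    so_amp_uv: float = 25.0
    sigma_band_uv: float = 0.0  # rms of a 12-16 Hz background component
    ripple_band_uv: float = 0.0  # rms of an 80-120 Hz Gaussian component
    band_mod_depth: float = 0.6  # relative depth of the slow envelope
    band_mod_freq_hz: float = 0.05  # corner of the envelope fluctuation
    #: ongoing sub-ripple high-frequency bursts on HIPP (amplitude-bounded,
    #: high duty cycle) emulating hippocampal gamma/HFO background
    hf_bg_rate_per_min: float = 100.0
    hf_bg_amp_range_uv: tuple[float, float] = (2.0, 5.0)
    hf_bg_dur_range_s: tuple[float, float] = (0.05, 0.3)


@dataclass
class SpindleConfig:
    freq_hz: float = 13.5  # centre frequency; per-event frequency varies
    #: half-range of the per-event frequency draw.  Real spindles vary in
    #: frequency from event to event; this also spreads the coupling
    #: delay's phase signature across the band, without which directional
    #: connectivity would rest on a ~1 Hz sliver around a pure tone.
    freq_jitter_hz: float = 1.25
    dur_range_s: tuple[float, float] = (1.0, 2.25)
    amp_uv: float = 18.0
    rate_per_min: float = 7.0  # uncoupled background spindles, per channel

    def __post_init__(self) -> None:
        lo, hi = self.dur_range_s
        if not (0.4 <= lo <= hi <= 3.0):
            raise ValueError("spindle durations must lie within [0.4, 3] s")
        if not (12.0 <= self.freq_hz - self.freq_jitter_hz
                and self.freq_hz + self.freq_jitter_hz <= 16.0):
            raise ValueError("spindle frequencies must lie within [12, 16] Hz")

    def draw_freq(self, rng: np.random.Generator) -> float:
        return rng.uniform(self.freq_hz - self.freq_jitter_hz,
                           self.freq_hz + self.freq_jitter_hz)


@dataclass
class RippleConfig:
    freq_hz: float = 90.0
    dur_range_s: tuple[float, float] = (0.12, 0.32)
    amp_uv: float = 28.0
    sharpwave_freq_hz: float = 3.0
    sharpwave_amp_uv: float = 40.0
    rate_per_min: float = 7.0

    def __post_init__(self) -> None:
        lo, hi = self.dur_range_s
        if not (0.038 <= lo <= hi <= 0.5):
            raise ValueError("ripple durations must lie within [0.038, 0.5] s")
        if not (80.0 <= self.freq_hz <= 120.0):
            raise ValueError("ripple frequency must lie within [80, 120] Hz")


@dataclass
class CouplingConfig:
    p_couple: float = 0.8  # probability a ripple is preceded by spindles
    lag_nc_s: float = 0.225  # NC spindle onset precedes ripple peak by this
    lag_hipp_s: float = 0.075  # HIPP spindle onset precedes ripple peak
    jitter_s: float = 0.01  # SD of lag jitter
    direction_delay_s: float = 0.020  # HIPP carrier delay relative to NC
    direction_mix: float = 0.9  # fraction of HIPP carrier copied from NC

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_couple <= 1.0:
            raise ValueError("p_couple must lie in [0, 1]")
        if not 0.0 <= self.direction_mix <= 1.0:
            raise ValueError("direction_mix must lie in [0, 1]")


@dataclass
class ArtifactInjectionConfig:
    n_amplitude: int = 0
    amplitude_uv: float = 900.0
    amplitude_dur_s: float = 0.3
    n_steps: int = 0
    step_uv: float = 400.0
    step_hold_s: float = 0.5
    n_hf_bursts: int = 0
    hf_freq_hz: float = 200.0
    hf_amp_uv: float = 60.0
    hf_dur_s: float = 0.15


@dataclass
class SimulationConfig:
    """Full parameterisation of one synthetic night."""

    duration_s: float = 1800.0
    fs: float = 1000.0
    background: BackgroundConfig = field(default_factory=BackgroundConfig)
    spindle_model: SpindleConfig = field(default_factory=SpindleConfig)
    ripple_model: RippleConfig = field(default_factory=RippleConfig)
    coupling: CouplingConfig = field(default_factory=CouplingConfig)
    #: slope linking coupled-spindle amplitude to ripple duration
    duration_effect: float = 0.0
    artifact_injection: ArtifactInjectionConfig = field(
        default_factory=ArtifactInjectionConfig
    )
    #: (stage, fraction-of-night) blocks; events are only placed in S2/SWS
    stage_blocks: tuple[tuple[str, float], ...] = (
        ("W", 0.05),
        ("S2", 0.40),
        ("SWS", 0.30),
        ("REM", 0.15),
        ("S2", 0.10),
    )
    epoch_len_s: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        top = max(self.ripple_model.freq_hz, self.artifact_injection.hf_freq_hz)
        if self.fs <= 2 * top:
            raise ValueError(
                f"fs={self.fs} must exceed twice the highest injected "
                f"frequency ({top} Hz)"
            )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Everything needed to score a detector against the generator."""

    events: pd.DataFrame  # EVENT_COLUMNS schema
    artifact_intervals: list[tuple[int, int, str]]  # (start, end) samples
    coupling_pairs: list[dict]  # ripple_id -> spindle ids (or None)

    def events_of(self, kind: str, channel: str | None = None) -> pd.DataFrame:
        sel = self.events[self.events["kind"] == kind]
        if channel is not None:
            sel = sel[sel["channel"] == channel]
        return sel.reset_index(drop=True)


# ---------------------------------------------------------------------------


def pink_noise(rng: np.random.Generator, n: int, fs: float, exponent: float,
               rms: float, f_min: float = 0.3) -> np.ndarray:
    """FFT-shaped Gaussian noise with power spectral density ~ 1/f^exponent.

    Content below ``f_min`` is suppressed to avoid unbounded drift.
    """
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spec = (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    shape = np.zeros_like(freqs)
    nz = freqs >= f_min
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    x *= rms / max(np.sqrt(np.mean(x**2)), 1e-30)
    return x


def band_noise(rng: np.random.Generator, n: int, fs: float,
               band: tuple[float, float], rms: float,
               mod_depth: float = 0.0, mod_freq_hz: float = 0.05) -> np.ndarray:
    """Band-limited Gaussian noise with a slowly fluctuating envelope.

    The envelope is low-pass noise (corner ``mod_freq_hz``) scaled to
    ``1 + mod_depth * z`` and floored at 0.05, so band power waxes and
    wanes on a tens-of-seconds timescale as in real NREM sleep.
    """
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spec = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    shape = ((freqs >= band[0]) & (freqs <= band[1])).astype(float)
    x = np.fft.irfft(spec * shape, n=n)
    if mod_depth > 0:
        espec = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
        eshape = ((freqs > 0) & (freqs <= mod_freq_hz)).astype(float)
        z = np.fft.irfft(espec * eshape, n=n)
        z /= max(np.sqrt(np.mean(z**2)), 1e-30)
        x *= np.maximum(1.0 + mod_depth * z, 0.05)
    x *= rms / max(np.sqrt(np.mean(x**2)), 1e-30)
    return x


def _build_hypnogram(cfg: SimulationConfig) -> Hypnogram:
    n_epochs = int(np.ceil(cfg.duration_s / cfg.epoch_len_s))
    fracs = np.array([f for _, f in cfg.stage_blocks], dtype=float)
    fracs = fracs / fracs.sum()
    counts = np.floor(fracs * n_epochs).astype(int)
    # distribute the remainder to the largest blocks
    for i in np.argsort(-fracs)[: n_epochs - counts.sum()]:
        counts[i] += 1
    stages: list[str] = []
    for (stage, _), c in zip(cfg.stage_blocks, counts):
        stages.extend([stage] * c)
    return Hypnogram(stages=stages[:n_epochs], epoch_len_s=cfg.epoch_len_s)


def _nrem_windows(hyp: Hypnogram, duration_s: float, margin_s: float) -> list[tuple[float, float]]:
    """Contiguous S2/SWS spans (seconds), shrunk by ``margin_s`` per side."""
    wins = []
    start = None
    for i, st in enumerate(hyp.stages):
        t0 = i * hyp.epoch_len_s
        is_nrem = st in ("S2", "SWS")
        if is_nrem and start is None:
            start = t0
        if (not is_nrem or i == len(hyp.stages) - 1) and start is not None:
            end = t0 if not is_nrem else min((i + 1) * hyp.epoch_len_s, duration_s)
            if end - start > 2 * margin_s:
                wins.append((start + margin_s, end - margin_s))
            start = None
    return wins


def _poisson_times(rng: np.random.Generator, windows: Sequence[tuple[float, float]],
                   rate_per_min: float, min_gap_s: float,
                   occupied: list[tuple[float, float]] | None = None) -> list[float]:
    """Homogeneous Poisson event times in the windows, thinned to keep a
    minimum gap between events (and from pre-occupied spans)."""
    occupied = list(occupied or [])
    rate = rate_per_min / 60.0
    times: list[float] = []
    for w0, w1 in windows:
        t = w0
        while True:
            t += rng.exponential(1.0 / rate) if rate > 0 else np.inf
            if t >= w1:
                break
            if all(abs(t - o0) > min_gap_s and abs(t - o1) > min_gap_s
                   and not (o0 - min_gap_s < t < o1 + min_gap_s)
                   for o0, o1 in occupied):
                times.append(t)
                occupied.append((t, t))
    return times


def _check_capacity(kind: str, rate_per_min: float, nrem_s: float,
                    mean_event_s: float, min_gap_s: float) -> None:
    expected = rate_per_min / 60.0 * nrem_s
    capacity = nrem_s / (mean_event_s + min_gap_s)
    if expected > 0.8 * capacity:
        raise ValueError(
            f"recording too short for requested {kind} rate of "
            f"{rate_per_min}/min: expected {expected:.0f} events but NREM "
            f"capacity is ~{capacity:.0f}"
        )


def _spindle_wave(t_rel: np.ndarray, dur: float, freq: float, amp: float,
                  phase: float) -> np.ndarray:
    env = hann(len(t_rel)) if len(t_rel) > 1 else np.ones_like(t_rel)
    return amp * env * np.sin(2 * np.pi * freq * t_rel + phase)


MIN_EVENT_GAP_S = 1.0


def generate_recording(
    config: SimulationConfig,
) -> tuple[Recording, GroundTruth, Hypnogram]:
    """Simulate one synthetic night.

    Returns the two-channel recording (NC, HIPP), the ground truth (injected
    events with exact timing, artifact intervals, coupling pairs) and the
    hypnogram.  Deterministic for a given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs

    hyp = _build_hypnogram(config)
    margin = 3.5  # keep events clear of stage-block edges for epoching
    windows = _nrem_windows(hyp, config.duration_s, margin)
    nrem_s = sum(w1 - w0 for w0, w1 in windows)
    if not windows:
        raise ValueError("hypnogram layout contains no usable NREM block")

    sp, rp, cpl = config.spindle_model, config.ripple_model, config.coupling
    if rp.rate_per_min > 0:
        _check_capacity("ripple", rp.rate_per_min, nrem_s,
                        np.mean(rp.dur_range_s), MIN_EVENT_GAP_S)
    if sp.rate_per_min > 0:
        _check_capacity("spindle", sp.rate_per_min, nrem_s,
                        np.mean(sp.dur_range_s), MIN_EVENT_GAP_S)

    bg = config.background
    nc = pink_noise(rng, n, fs, bg.pink_exponent, bg.rms_uv)
    hipp = pink_noise(rng, n, fs, bg.pink_exponent, bg.rms_uv)
    so_phase = rng.uniform(0, 2 * np.pi, size=2)
    nc += bg.so_amp_uv * np.sin(2 * np.pi * bg.so_freq_hz * t + so_phase[0])
    hipp += bg.so_amp_uv * np.sin(2 * np.pi * bg.so_freq_hz * t + so_phase[1])
    if bg.sigma_band_uv > 0:
        for sig_arr in (nc, hipp):
            sig_arr += band_noise(rng, n, fs, (12.0, 16.0), bg.sigma_band_uv,
                                  bg.band_mod_depth, bg.band_mod_freq_hz)
    if bg.ripple_band_uv > 0:
        hipp += band_noise(rng, n, fs, (80.0, 120.0), bg.ripple_band_uv,
                           bg.band_mod_depth, bg.band_mod_freq_hz)
    if bg.hf_bg_rate_per_min > 0:
        n_bursts = rng.poisson(bg.hf_bg_rate_per_min / 60.0 * config.duration_s)
        for _ in range(n_bursts):
            dur_b = rng.uniform(*bg.hf_bg_dur_range_s)
            t0 = rng.uniform(0, config.duration_s - dur_b)
            b0 = int(t0 * fs)
            b1 = min(b0 + int(dur_b * fs), n)
            if b1 - b0 < 4:
                continue
            f_b = rng.uniform(80.0, 120.0)
            amp_b = rng.uniform(*bg.hf_bg_amp_range_uv)
            hipp[b0:b1] += amp_b * hann(b1 - b0) * np.sin(
                2 * np.pi * f_b * (t[b0:b1] - t0) + rng.uniform(0, 2 * np.pi))

    rows: list[dict] = []
    coupling_pairs: list[dict] = []
    next_id = 0

    def _add_event(channel: str, kind: str, onset: float, dur: float,
                   peak: float, amp: float) -> int:
        nonlocal next_id
        rows.append(dict(id=next_id, channel=channel, kind=kind, onset_s=onset,
                         offset_s=onset + dur, peak_s=peak, duration_s=dur,
                         peak_amp_uv=amp))
        next_id += 1
        return next_id - 1

    # --- ripples (HIPP) with optional coupled spindles ---------------------
    ripple_centers = _poisson_times(
        rng, windows, rp.rate_per_min,
        MIN_EVENT_GAP_S + max(rp.dur_range_s), occupied=None)
    dur_mid = 0.5 * (rp.dur_range_s[0] + rp.dur_range_s[1])
    occupied_nc: list[tuple[float, float]] = []
    occupied_hipp: list[tuple[float, float]] = []

    for center in ripple_centers:
        dur_r = rng.uniform(*rp.dur_range_s)
        onset_r = center - dur_r / 2
        k0 = int(round(onset_r * fs))
        k1 = k0 + int(round(dur_r * fs))
        tt = t[k0:k1] - center
        env = tukey(k1 - k0, alpha=0.5)
        phase_r = rng.uniform(0, 2 * np.pi)
        ripple_wave = rp.amp_uv * env * np.sin(2 * np.pi * rp.freq_hz * tt + phase_r)
        # force a clear positive carrier peak at the centre for peak locking
        hipp[k0:k1] += ripple_wave
        # one sharp-wave cycle under the ripple: negative half-wave then rebound
        sw_len = int(round(fs / rp.sharpwave_freq_hz))
        s0 = int(round(center * fs)) - sw_len // 2
        tt_sw = (np.arange(sw_len) - sw_len / 2) / fs
        sw = -rp.sharpwave_amp_uv * np.sin(
            2 * np.pi * rp.sharpwave_freq_hz * (tt_sw + 1.0 / (4 * rp.sharpwave_freq_hz))
        ) * hann(sw_len)
        hipp[s0:s0 + sw_len] += sw[: max(0, min(sw_len, n - s0))]
        rid = _add_event("HIPP", "ripple", onset_r, dur_r, center, rp.amp_uv)
        occupied_hipp.append((onset_r, onset_r + dur_r))

        pair = dict(ripple_id=rid, nc_spindle_id=None, hipp_spindle_id=None)
        if rng.uniform() < cpl.p_couple:
            amp_scale = 1.0
            if config.duration_effect != 0.0:
                amp_scale = max(
                    0.1, 1.0 + config.duration_effect * (dur_r - dur_mid) / dur_mid
                )
            dur_nc = rng.uniform(*sp.dur_range_s)
            dur_h = rng.uniform(*sp.dur_range_s)
            # truncated-normal jitter keeps every lag within +-3 sigma
            jit = np.clip(rng.normal(0, cpl.jitter_s, size=2),
                          -3 * cpl.jitter_s, 3 * cpl.jitter_s)
            on_nc = center - cpl.lag_nc_s + jit[0]
            on_h = center - cpl.lag_hipp_s + jit[1]
            phase = rng.uniform(0, 2 * np.pi)
            amp_nc = sp.amp_uv * amp_scale
            amp_h = sp.amp_uv * amp_scale
            f_ev = sp.draw_freq(rng)  # shared carrier frequency

            j0 = int(round(on_nc * fs))
            j1 = j0 + int(round(dur_nc * fs))
            nc[j0:j1] += _spindle_wave(t[j0:j1] - on_nc, dur_nc, f_ev,
                                       amp_nc, phase)
            sid_nc = _add_event("NC", "spindle", on_nc, dur_nc,
                                on_nc + dur_nc / 2, amp_nc)
            occupied_nc.append((on_nc, on_nc + dur_nc))

            # HIPP carrier: delayed copy of the NC carrier (direction_mix)
            # plus an independent-phase component, under HIPP's own envelope
            m0 = int(round(on_h * fs))
            m1 = m0 + int(round(dur_h * fs))
            tt_h = t[m0:m1]
            env_h = hann(m1 - m0)
            carrier_copy = np.sin(
                2 * np.pi * f_ev * (tt_h - cpl.direction_delay_s - on_nc) + phase
            )
            carrier_own = np.sin(
                2 * np.pi * f_ev * (tt_h - on_h) + rng.uniform(0, 2 * np.pi)
            )
            mixture = (cpl.direction_mix * carrier_copy
                       + (1 - cpl.direction_mix) * carrier_own)
            # same-frequency carriers sum to a sine whose amplitude depends
            # on their relative phase; renormalise so every coupled spindle
            # has exactly amp_h peak amplitude
            m_amp = np.sqrt(np.mean(mixture**2)) * np.sqrt(2.0)
            if m_amp > 1e-9:
                mixture /= m_amp
            hipp[m0:m1] += amp_h * env_h * mixture
            sid_h = _add_event("HIPP", "spindle", on_h, dur_h,
                               on_h + dur_h / 2, amp_h)
            occupied_hipp.append((on_h, on_h + dur_h))
            pair.update(nc_spindle_id=sid_nc, hipp_spindle_id=sid_h)
        coupling_pairs.append(pair)

    # --- uncoupled background spindles, per channel -------------------------
    for ch_name, signal, occupied in (
        ("NC", nc, occupied_nc), ("HIPP", hipp, occupied_hipp),
    ):
        occ = occupied + [(r - 1.0, r + 1.0) for r in ripple_centers]
        for onset in _poisson_times(rng, windows, sp.rate_per_min,
                                    MIN_EVENT_GAP_S + max(sp.dur_range_s),
                                    occupied=occ):
            dur = rng.uniform(*sp.dur_range_s)
            j0 = int(round(onset * fs))
            j1 = min(j0 + int(round(dur * fs)), n)
            if j1 - j0 < 2:
                continue
            signal[j0:j1] += _spindle_wave(
                t[j0:j1] - onset, dur, sp.draw_freq(rng), sp.amp_uv,
                rng.uniform(0, 2 * np.pi))
            _add_event(ch_name, "spindle", onset, dur, onset + dur / 2, sp.amp_uv)

    events = make_event_list(rows) if rows else pd.DataFrame(columns=EVENT_COLUMNS)

    rec = Recording(
        data=np.vstack([nc, hipp]),
        fs=fs,
        channel_names=["NC", "HIPP"],
        channel_roles={"NC": "NC", "HIPP": "HIPP"},
    )

    truth = GroundTruth(events=events, artifact_intervals=[],
                        coupling_pairs=coupling_pairs)

    if _total_artifacts(config.artifact_injection) > 0:
        rec, art_intervals = inject_artifacts(
            rec, config.artifact_injection, seed=rng.integers(0, 2**31),
            avoid=_event_spans(events, pad_s=5.0), windows=windows)
        truth.artifact_intervals = art_intervals

    _validate_truth(truth, config)
    return rec, truth, hyp


def _event_spans(events: pd.DataFrame, pad_s: float) -> list[tuple[float, float]]:
    return [(r.onset_s - pad_s, r.offset_s + pad_s) for r in events.itertuples()]


def _total_artifacts(cfg: ArtifactInjectionConfig) -> int:
    return cfg.n_amplitude + cfg.n_steps + cfg.n_hf_bursts


def inject_artifacts(
    recording: Recording,
    config: ArtifactInjectionConfig,
    seed: int,
    avoid: Sequence[tuple[float, float]] = (),
    windows: Sequence[tuple[float, float]] | None = None,
) -> tuple[Recording, list[tuple[int, int, str]]]:
    """Add synthetic artifacts to the HIPP channel of a recording.

    Three classes mirror the automated rejection rules downstream:
    ``amplitude`` (boxcar excursions beyond +-750 uV), ``gradient``
    (single-sample step discontinuities) and ``hf_burst`` (>150 Hz noise
    bursts of >= 100 ms).  Positions are recorded as ground truth in samples.
    """
    if recording.n_samples == 0:
        raise ValueError("recording is empty")
    rng = np.random.default_rng(seed)
    fs = recording.fs
    n = recording.n_samples
    data = recording.data.copy()
    sig = data[recording.channel_names.index(
        recording.role_channel_name("HIPP"))]
    if windows is None:
        windows = [(1.0, n / fs - 1.0)]

    taken = list(avoid)
    intervals: list[tuple[int, int, str]] = []

    def _place(dur_s: float) -> float:
        for _ in range(2000):
            w0, w1 = windows[rng.integers(len(windows))]
            if w1 - w0 <= dur_s:
                continue
            t0 = rng.uniform(w0, w1 - dur_s)
            if all(t0 + dur_s < a0 or t0 > a1 for a0, a1 in taken):
                taken.append((t0 - 2.0, t0 + dur_s + 2.0))
                return t0
        raise ValueError(
            "could not place requested artifacts without overlap; reduce "
            "counts or event rates")

    for _ in range(config.n_amplitude):
        t0 = _place(config.amplitude_dur_s)
        k0, k1 = int(t0 * fs), int((t0 + config.amplitude_dur_s) * fs)
        sig[k0:k1] += config.amplitude_uv * tukey(k1 - k0, 0.2)
        intervals.append((k0, k1, "amplitude"))

    for _ in range(config.n_steps):
        t0 = _place(config.step_hold_s + 1.0)
        k0 = int(t0 * fs)
        hold = int(config.step_hold_s * fs)
        ramp = int(1.0 * fs)
        shape = np.concatenate([
            np.full(hold, config.step_uv),
            config.step_uv * 0.5 * (1 + np.cos(np.linspace(0, np.pi, ramp))),
        ])
        k1 = min(k0 + len(shape), n)
        sig[k0:k1] += shape[: k1 - k0]  # sharp onset, smooth decay
        intervals.append((k0, k0 + 1, "gradient"))

    for _ in range(config.n_hf_bursts):
        t0 = _place(config.hf_dur_s)
        k0, k1 = int(t0 * fs), int((t0 + config.hf_dur_s) * fs)
        tt = np.arange(k1 - k0) / fs
        sig[k0:k1] += config.hf_amp_uv * tukey(k1 - k0, 0.25) * np.sin(
            2 * np.pi * config.hf_freq_hz * tt)
        intervals.append((k0, k1, "hf_burst"))

    out = Recording(data=data, fs=fs, channel_names=list(recording.channel_names),
                    channel_roles=dict(recording.channel_roles),
                    start_time=recording.start_time)
    return out, intervals


def _validate_truth(truth: GroundTruth, config: SimulationConfig) -> None:
    ev = truth.events
    if len(ev) and (ev["onset_s"].min() < 0 or ev["offset_s"].max() > config.duration_s):
        raise AssertionError("injected event extends past recording bounds")
    by_id = ev.set_index("id") if len(ev) else None
    for pair in truth.coupling_pairs:
        if pair["nc_spindle_id"] is None:
            continue
        rid = pair["ripple_id"]
        peak = by_id.loc[rid, "peak_s"]
        for key, lag in (("nc_spindle_id", config.coupling.lag_nc_s),
                         ("hipp_spindle_id", config.coupling.lag_hipp_s)):
            onset = by_id.loc[pair[key], "onset_s"]
            if abs((peak - onset) - lag) > 3 * config.coupling.jitter_s + 2e-3:
                raise AssertionError(
                    f"coupled spindle lag {(peak - onset):.3f} deviates from "
                    f"{lag} by more than 3 sigma jitter")
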