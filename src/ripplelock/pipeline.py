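"""Config-driven orchestration of the full ripple-locked analysis chain.

Stages, in order: artifact rejection → NREM masking → spindle/ripple
detection → matched control events → ripple-locked TFR contrast with
cluster permutation → spindle-band coherence (map, window mean, z) →
directional PDC z time course → peri-ripple spindle-onset histograms →
duration tertile analyses.  The control sets are processed one at a time
so the 100-set TFRs never reside in memory simultaneously.

Everything is deterministic under the config seed; each run writes the
resolved config next to its outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import artifacts as art
from . import detect as det
from . import connectivity as conn
from . import stats as st
from .controls import ControlParams, draw_control_sets, ControlEventSets
from .io import (Recording, Hypnogram, nrem_mask, write_events, write_json,
                 write_recording, write_hypnogram)
from .simulate import SimulationConfig, generate_recording, RippleConfig
from .spectral import build_wavelet_spec, compute_tfr, extract_epochs, TFRStack

logger = logging.getLogger(__name__)

EPOCH_HALF_S = 3.0  # raw segment half-length, guarantees wavelet support
ANALYSIS_T_RANGE = (-1.0, 1.0)
COHERENCE_WINDOW_T = (-0.22, 0.46)
COHERENCE_WINDOW_F = (11.5, 18.0)
SPINDLE_BAND = (12.0, 16.0)


@dataclass
class AnalysisConfig:
    """Resolved parameter set for one full analysis run."""

    seed: int = 0
    spindle_params: det.DetectorParams = field(
        default_factory=lambda: det.SPINDLE_PARAMS)
    ripple_params: det.DetectorParams = field(
        default_factory=lambda: det.RIPPLE_PARAMS)
    control_params: ControlParams = field(default_factory=ControlParams)
    freq_range: tuple[float, float] = (1.0, 20.0)
    freq_step: float = 0.5
    time_step_s: float = 0.020
    pdc_window_s: float = 0.512
    band: tuple[float, float] = SPINDLE_BAND
    coherence_window_t: tuple[float, float] = COHERENCE_WINDOW_T
    coherence_window_f: tuple[float, float] = COHERENCE_WINDOW_F
    alpha: float = 0.05
    n_permutations: int = 1000
    histogram_bin_s: float = 0.05
    histogram_range_s: float = 0.5

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def coupling_night_config(seed: int = 0, duration_s: float = 3000.0,
                          duration_effect: float = 0.0) -> SimulationConfig:
    """Synthetic night tuned for control-set and coupling analyses.

    Uses a clinical-range ripple rate (1.5/min) and shorter ripples so
    that 100 non-overlapping duration-matched control sets fit into the
    night's clean NREM time; the default night's denser ripples maximise
    detector recall instead but leave no room for the surrogate draw.
    """
    return SimulationConfig(
        duration_s=duration_s, seed=seed,
        ripple_model=RippleConfig(rate_per_min=1.5, dur_range_s=(0.08, 0.2),
                                  amp_uv=20.0),
        duration_effect=duration_effect,
    )


@dataclass
class NightAnalysis:
    """All per-night intermediate products and results."""

    recording: Recording
    hypnogram: Hypnogram
    mask: art.ArtifactMask
    clean_nrem: np.ndarray
    spindles_nc: pd.DataFrame
    spindles_hipp: pd.DataFrame
    ripples: pd.DataFrame
    densities: dict
    controls: ControlEventSets | None = None
    results: dict = field(default_factory=dict)


def detect_stage(recording: Recording, hypnogram: Hypnogram,
                 config: AnalysisConfig) -> NightAnalysis:
    """Artifact rejection, NREM masking and event detection."""
    fs = recording.fs
    masks = [art.detect_all(recording.channel(role), fs, hypnogram)
             for role in ("NC", "HIPP")]
    mask = art.combine_masks(*masks)
    nrem = nrem_mask(hypnogram, fs, recording.n_samples)
    clean = nrem & ~mask.mask

    spindles_nc = det.detect_events(recording.channel("NC"), fs, mask, nrem,
                                    config.spindle_params, "NC")
    spindles_hipp = det.detect_events(recording.channel("HIPP"), fs, mask,
                                      nrem, config.spindle_params, "HIPP")
    ripples = det.detect_events(recording.channel("HIPP"), fs, mask, nrem,
                                config.ripple_params, "HIPP")
    clean_min = clean.sum() / fs / 60.0
    densities = dict(
        clean_nrem_min=float(clean_min),
        spindle_nc_per_min=det.event_density(spindles_nc, clean.sum() / fs),
        spindle_hipp_per_min=det.event_density(spindles_hipp, clean.sum() / fs),
        ripple_per_min=det.event_density(ripples, clean.sum() / fs),
    )
    logger.info("detected %d NC spindles, %d HIPP spindles, %d ripples "
                "(%.1f min clean NREM)", len(spindles_nc),
                len(spindles_hipp), len(ripples), clean_min)
    return NightAnalysis(recording=recording, hypnogram=hypnogram, mask=mask,
                         clean_nrem=clean, spindles_nc=spindles_nc,
                         spindles_hipp=spindles_hipp, ripples=ripples,
                         densities=densities)


def _tfr_at(night: NightAnalysis, centers_s: np.ndarray,
            config: AnalysisConfig, lock: str) -> tuple[TFRStack, np.ndarray]:
    spec = build_wavelet_spec(config.freq_range, config.freq_step,
                              config.time_step_s)
    epochs, kept = extract_epochs(night.recording.data, night.recording.fs,
                                  centers_s, EPOCH_HALF_S)
    tfr = compute_tfr(epochs, night.recording.fs, spec, lock=lock)
    return tfr, kept


_TFR_DECIM = 5  # continuous-TFR grid: 5 ms; event slices step 4x -> 20 ms


def _continuous_tfr(night: NightAnalysis, config: AnalysisConfig):
    from .spectral import compute_tfr_continuous

    spec = build_wavelet_spec(config.freq_range, config.freq_step,
                              config.time_step_s)
    coeffs, decim = compute_tfr_continuous(night.recording.data,
                                           night.recording.fs, spec,
                                           decim=_TFR_DECIM)
    return coeffs, decim, spec


def connectivity_stage(night: NightAnalysis, config: AnalysisConfig) -> dict:
    """Ripple-locked TFR contrast, coherence, PDC and onset histograms.

    Control sets are streamed: per set the TFR is computed, reduced to the
    per-set scalars/time courses and the running sum for the paired
    average, then released.
    """
    if len(night.ripples) == 0:
        return dict(status="no ripples detected; ripple-locked analyses "
                           "not possible")
    if night.controls is None:
        night.controls = draw_control_sets(
            night.ripples, night.clean_nrem, night.recording.fs,
            config.control_params)

    from .spectral import slice_continuous_tfr

    ctfr, decim, spec = _continuous_tfr(night, config)
    step_mult = max(int(round(config.time_step_s * night.recording.fs
                              / decim)), 1)
    fs = night.recording.fs

    def _slice(centers: np.ndarray, lock: str):
        return slice_continuous_tfr(ctfr, decim, fs, centers, EPOCH_HALF_S,
                                    np.asarray(spec.freqs_hz), step_mult,
                                    lock)

    rip_peaks = np.asarray(night.ripples["peak_s"], float)
    tfr_rip, kept = _slice(rip_peaks, "ripple_peak")
    kept_ids = np.asarray(night.ripples["id"])[kept]
    nc, hipp = tfr_rip.channel(0), tfr_rip.channel(1)

    coh_map = conn.coherence(nc, hipp)
    coh_scalar = conn.window_mean(coh_map, tfr_rip.freq_axis_hz,
                                  tfr_rip.time_axis_s,
                                  config.coherence_window_t,
                                  config.coherence_window_f)
    coh_tc = conn.band_mean(coh_map, tfr_rip.freq_axis_hz, config.band)
    tsel = ((tfr_rip.time_axis_s >= ANALYSIS_T_RANGE[0])
            & (tfr_rip.time_axis_s <= ANALYSIS_T_RANGE[1]))

    pdc_rip = conn.pdc(tfr_rip, window_len_s=config.pdc_window_s,
                       step_s=config.time_step_s, t_range_s=ANALYSIS_T_RANGE)

    # stream over control sets
    power_sum = np.zeros((len(kept_ids), 2) + tfr_rip.power.shape[2:])
    power_n = np.zeros_like(power_sum)
    coh_scalars, coh_tcs, pdc_ctl = [], [], []
    ctl_locks = []
    by_set = night.controls.sets.groupby("set_id")
    for set_id, rows in by_set:
        rows = rows.set_index("ripple_id").loc[kept_ids]
        centers = np.asarray(rows["center_s"], float)
        ctl_locks.append(centers)
        tfr_ctl, kept_c = _slice(centers, "control_center")
        if len(kept_c) != len(centers):
            raise RuntimeError("control epoch fell outside the recording")
        p = tfr_ctl.power
        good = np.isfinite(p)
        power_sum += np.where(good, p, 0.0)
        power_n += good
        c_nc, c_h = tfr_ctl.channel(0), tfr_ctl.channel(1)
        cmap = conn.coherence(c_nc, c_h)
        coh_scalars.append(conn.window_mean(cmap, tfr_ctl.freq_axis_hz,
                                            tfr_ctl.time_axis_s,
                                            config.coherence_window_t,
                                            config.coherence_window_f))
        coh_tcs.append(conn.band_mean(cmap, tfr_ctl.freq_axis_hz, config.band))
        pdc_ctl.append(conn.pdc(tfr_ctl, window_len_s=config.pdc_window_s,
                                step_s=config.time_step_s,
                                t_range_s=ANALYSIS_T_RANGE))

    with np.errstate(invalid="ignore", divide="ignore"):
        ctl_power_mean = np.where(power_n > 0, power_sum / power_n, np.nan)

    # paired cluster test on log power within the analysis window
    fsel = np.ones(len(tfr_rip.freq_axis_hz), bool)
    ev_p = tfr_rip.power[:, :, :, tsel]
    ct_p = ctl_power_mean[:, :, :, tsel]
    cluster = {}
    for ci, ch in enumerate(("NC", "HIPP")):
        cluster[ch] = st.cluster_permutation(
            np.log10(np.maximum(ev_p[:, ci][:, fsel], 1e-300)),
            np.log10(np.maximum(ct_p[:, ci][:, fsel], 1e-300)),
            alpha_cluster=config.alpha, n_permutations=config.n_permutations,
            seed=config.seed)

    # z-statistics against the control distribution
    coh_z = st.z_vs_controls(coh_scalar, np.array(coh_scalars))
    ctl_tc = np.stack(coh_tcs)
    with np.errstate(invalid="ignore", divide="ignore"):
        coh_tc_z = (coh_tc - ctl_tc.mean(0)) / ctl_tc.std(0, ddof=1)
    direction = conn.pdc_direction_timecourse(pdc_rip, pdc_ctl, config.band)

    hist = {}
    for ch, spindles in (("NC", night.spindles_nc),
                         ("HIPP", night.spindles_hipp)):
        if len(spindles):
            hist[ch] = st.spindle_onset_histogram(
                spindles, rip_peaks[kept], ctl_locks,
                bin_s=config.histogram_bin_s,
                range_s=config.histogram_range_s)

    return dict(
        tfr_times=tfr_rip.time_axis_s, tfr_freqs=tfr_rip.freq_axis_hz,
        kept_ripple_ids=kept_ids,
        ripple_power=tfr_rip.power, control_power_mean=ctl_power_mean,
        coherence_map=coh_map, coherence_scalar=coh_scalar,
        coherence_z=coh_z, coherence_tc=coh_tc,
        coherence_tc_z=coh_tc_z, coherence_tc_times=tfr_rip.time_axis_s,
        pdc=pdc_rip, pdc_direction=direction, cluster=cluster,
        histograms=hist,
    )


def tertile_stage(night: NightAnalysis, config: AnalysisConfig,
                  results: dict) -> dict:
    """Duration tertile split and duration-power association (one night
    treated as one patient; multi-night studies concatenate these)."""
    ripples = night.ripples
    if len(ripples) < 3:
        return dict(status="too few ripples for tertile analyses")
    kept_ids = results["kept_ripple_ids"]
    rip = ripples.set_index("id").loc[kept_ids].reset_index()
    short, long, bounds = st.tertile_split(rip)

    # spindle-band window power per ripple epoch (NC channel)
    freqs = results["tfr_freqs"]
    times = results["tfr_times"]
    fsel = (freqs >= config.band[0]) & (freqs <= config.band[1])
    tsel = ((times >= config.coherence_window_t[0])
            & (times <= config.coherence_window_t[1]))
    power = results["ripple_power"]  # (n_ev, 2, f, t)
    win_power = np.nanmean(power[:, :, fsel][:, :, :, tsel], axis=(2, 3))
    out = dict(thresholds=bounds, n_short=len(short), n_long=len(long))
    idx = {rid: i for i, rid in enumerate(kept_ids)}
    for ci, ch in enumerate(("NC", "HIPP")):
        p_short = win_power[[idx[r] for r in short["id"]], ci]
        p_long = win_power[[idx[r] for r in long["id"]], ci]
        out[f"long_vs_short_{ch}"] = st.long_vs_short_power_test(
            p_long, p_short)
        out[f"duration_power_corr_{ch}"] = dict(zip(
            ("r", "p"), _single_spearman(rip["duration_s"], win_power[:, ci])))
    return out


def _single_spearman(x, y):
    from scipy.stats import spearmanr
    r, p = spearmanr(np.asarray(x, float), np.asarray(y, float))
    return float(r), float(p)


def run_full_analysis(recording: Recording, hypnogram: Hypnogram,
                      config: AnalysisConfig,
                      out_dir: str | Path | None = None) -> NightAnalysis:
    """Run the complete analysis chain on one recording."""
    night = detect_stage(recording, hypnogram, config)
    res = connectivity_stage(night, config)
    night.results = res
    if "status" not in res:
        night.results["tertiles"] = tertile_stage(night, config, res)
    if out_dir is not None:
        write_report(night, config, Path(out_dir))
    return night


def write_report(night: NightAnalysis, config: AnalysisConfig,
                 out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_events(night.spindles_nc, out_dir / "spindles_nc.tsv")
    write_events(night.spindles_hipp, out_dir / "spindles_hipp.tsv")
    write_events(night.ripples, out_dir / "ripples.tsv")
    if night.controls is not None:
        night.controls.sets.to_csv(out_dir / "control_events.tsv", sep="\t",
                                   index=False)
    pd.DataFrame(night.mask.intervals(),
                 columns=["start_sample", "end_sample", "classes"]).to_csv(
        out_dir / "artifact_intervals.tsv", sep="\t", index=False)
    write_json(dict(config.to_dict()), out_dir / "config_resolved.json")
    write_json(_summary(night, config), out_dir / "report.json")


def _summary(night: NightAnalysis, config: AnalysisConfig) -> dict:
    res = night.results
    out = dict(densities=night.densities,
               n_events=dict(spindles_nc=len(night.spindles_nc),
                             spindles_hipp=len(night.spindles_hipp),
                             ripples=len(night.ripples)),
               masked_fraction=float(night.mask.mask.mean()))
    if "status" in res:
        out["status"] = res["status"]
        return out
    coh_z = res["coherence_z"]
    out["coherence"] = dict(window_mean=res["coherence_scalar"],
                            z=coh_z.value, p=coh_z.p_two_sided)
    d = res["pdc_direction"]
    tsel = np.abs(d["times_s"]) <= 0.3
    out["pdc"] = dict(peak_z_diff=float(np.nanmax(d["z_diff"])),
                      z_diff_near_ripple=float(np.nanmax(d["z_diff"][tsel])))
    out["clusters"] = {
        ch: dict(n_significant=len(c.significant(config.alpha)),
                 min_p=(min((cl["p_corrected"] for cl in c.clusters),
                            default=1.0)))
        for ch, c in res["cluster"].items()}
    if "histograms" in res:
        out["histogram_peaks_s"] = {
            ch: float(h["bin_centers"][int(np.argmax(h["hist"]))])
            for ch, h in res["histograms"].items()}
    if "tertiles" in res:
        t = res["tertiles"]
        out["tertiles"] = {k: v for k, v in t.items()
                           if k in ("thresholds", "n_short", "n_long")}
        for key in ("long_vs_short_NC", "long_vs_short_HIPP"):
            if key in t:
                out["tertiles"][key] = dict(t=t[key]["t"], p=t[key]["p"])
    return out


def simulate_night(sim_config: SimulationConfig, out_dir: str | Path | None = None
                   ) -> tuple[Recording, "GroundTruth", Hypnogram]:
    """Generate a synthetic night and optionally persist it (EDF + truth)."""
    from .simulate import GroundTruth  # noqa: F401 (typing)

    rec, truth, hyp = generate_recording(sim_config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_recording(rec, out / "recording.edf", "edf")
        write_hypnogram(hyp, out / "hypnogram.txt")
        write_events(truth.events, out / "truth_events.tsv")
        write_json(dict(coupling_pairs=truth.coupling_pairs,
                        artifact_intervals=[list(x) for x in
                                            truth.artifact_intervals]),
                   out / "truth_sidecar.json")
        write_json(sim_config.to_dict(), out / "sim_config.json")
    return rec, truth, hyp
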