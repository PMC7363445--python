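"""Statistical machinery for ripple-locked analyses.

Scalar connectivity values are tested against the empirical null formed by
the 100 control-event sets via a z-statistic,
``z = (empirical − mean(controls)) / std(controls)``, significant beyond
|z| > 1.96.  Time-frequency power contrasts between ripple-locked and
averaged-control TFRs use a cluster-based permutation procedure (paired t
per cell, 4-connected supra-threshold clustering, cluster-mass statistic,
sign-flip null).  Event-level analyses cover peri-ripple histograms of
spindle onsets, per-patient duration tertile splits, duration–power
correlations, and event contingency rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class ZStat:
    value: float
    p_two_sided: float
    empirical: float
    control_mean: float
    control_sd: float
    n_controls: int

    @property
    def significant(self) -> bool:
        return abs(self.value) > 1.96


def z_vs_controls(empirical: float, controls: np.ndarray) -> ZStat:
    """z-statistic of an empirical scalar against its control distribution."""
    controls = np.asarray(controls, float)
    controls = controls[np.isfinite(controls)]
    if len(controls) < 2:
        raise ValueError("need at least two control values")
    m = controls.mean()
    sd = controls.std(ddof=1)
    if sd <= 0:
        raise ValueError("control distribution has zero spread")
    z = (empirical - m) / sd
    return ZStat(value=float(z), p_two_sided=float(2 * sps.norm.sf(abs(z))),
                 empirical=float(empirical), control_mean=float(m),
                 control_sd=float(sd), n_controls=len(controls))


@dataclass
class ClusterResult:
    clusters: list[dict]  # {cells, mass, p_corrected}
    t_map: np.ndarray
    threshold_alpha: float
    n_permutations: int

    def significant(self, alpha: float = 0.05) -> list[dict]:
        return [c for c in self.clusters if c["p_corrected"] < alpha]


def cluster_permutation(event_stack: np.ndarray, control_stack: np.ndarray,
                        alpha_cluster: float = 0.05,
                        n_permutations: int = 1000,
                        seed: int = 0, tail: int = 0) -> ClusterResult:
    """Cluster-based permutation test of paired (event, control) maps.

    ``event_stack``/``control_stack``: (n_pairs, n_freqs, n_times), pair i
    being one ripple and its control averaged over the 100 sets.  Per-cell
    paired t-values are thresholded at the ``alpha_cluster`` quantile,
    4-connected clusters formed, cluster mass (summed t) compared against a
    within-pair sign-flip null (max-mass distribution).
    """
    from mne.stats import permutation_cluster_1samp_test

    ev = np.asarray(event_stack, float)
    ct = np.asarray(control_stack, float)
    if ev.shape != ct.shape:
        raise ValueError("paired stacks must have identical shape")
    if ev.shape[0] < 5:
        raise ValueError("need at least 5 pairs for the permutation test")
    diff = ev - ct
    # NaN cells (invalid wavelet support) carry no evidence; zero
    # contributes nothing to paired t against zero
    diff = np.nan_to_num(diff, nan=0.0)
    df = diff.shape[0] - 1
    if tail == 0:
        thresh = sps.t.ppf(1 - alpha_cluster / 2, df)
    else:
        thresh = tail * sps.t.ppf(1 - alpha_cluster, df)
    t_obs, clusters, p_vals, _ = permutation_cluster_1samp_test(
        diff, threshold=thresh, n_permutations=n_permutations, tail=tail,
        adjacency=None, out_type="mask", rng=np.random.default_rng(seed),
        verbose="error")
    out = []
    for mask, p in zip(clusters, p_vals):
        out.append(dict(cells=mask, mass=float(np.sum(t_obs[mask])),
                        p_corrected=float(p)))
    out.sort(key=lambda c: c["p_corrected"])
    return ClusterResult(clusters=out, t_map=t_obs,
                         threshold_alpha=alpha_cluster,
                         n_permutations=n_permutations)


def spindle_onset_histogram(spindles: pd.DataFrame, ripple_peaks_s: np.ndarray,
                            control_peaks_per_set: list[np.ndarray] | None = None,
                            bin_s: float = 0.05, range_s: float = 0.5) -> dict:
    """Peri-event histogram of spindle onsets around ripple peaks.

    Counts spindle onsets in 50 ms bins within ±0.5 s of each ripple peak,
    normalised by the total number of detected spindle onsets × 100.  When
    control peak sets are given, per-bin z-values against the control
    histograms are added (significant beyond z > 1.96).  Onsets may count
    toward several ripples when windows overlap.
    """
    if len(spindles) == 0:
        raise ValueError("no spindles supplied")
    onsets = np.asarray(spindles["onset_s"], float)
    edges = np.arange(-range_s, range_s + bin_s / 2, bin_s)

    def _hist(locks: np.ndarray) -> np.ndarray:
        rel = (onsets[None, :] - np.asarray(locks, float)[:, None]).ravel()
        counts, _ = np.histogram(rel, bins=edges)
        return counts / len(onsets) * 100.0

    hist = _hist(ripple_peaks_s)
    out = dict(hist=hist, bin_edges=edges,
               bin_centers=(edges[:-1] + edges[1:]) / 2)
    if control_peaks_per_set is not None:
        ctl = np.stack([_hist(locks) for locks in control_peaks_per_set])
        mean, sd = ctl.mean(axis=0), ctl.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (hist - mean) / sd
        out.update(control_mean=mean, control_sd=sd, z=z,
                   significant=np.abs(z) > 1.96)
    return out


def tertile_split(ripples: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, tuple[float, float]]:
    """Split one patient's ripples into short/long duration tertiles.

    Boundaries are the 1/3 and 2/3 linear-interpolated duration quantiles;
    events tied exactly on a boundary go to the (discarded) middle tertile,
    keeping the short/long groups conservative.
    """
    if len(ripples) < 3:
        raise ValueError("need at least 3 ripples for a tertile split")
    dur = np.asarray(ripples["duration_s"], float)
    lo, hi = np.quantile(dur, [1 / 3, 2 / 3])
    short = ripples[dur < lo].reset_index(drop=True)
    long = ripples[dur > hi].reset_index(drop=True)
    return short, long, (float(lo), float(hi))


def long_vs_short_power_test(power_long: np.ndarray, power_short: np.ndarray
                             ) -> dict:
    """One-sided independent-samples t-test for long > short power."""
    a = np.asarray(power_long, float)
    b = np.asarray(power_short, float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 events")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("degenerate variance in both groups")
    t, p = sps.ttest_ind(a, b, alternative="greater")
    return dict(t=float(t), p=float(p), df=len(a) + len(b) - 2,
                mean_long=float(a.mean()), mean_short=float(b.mean()))


_FISHER_CLIP = 0.999999


def duration_power_correlation(per_patient: list[tuple[np.ndarray, np.ndarray]]
                               ) -> dict:
    """Group test of the ripple-duration × spindle-power association.

    ``per_patient`` holds (durations, window powers) per patient; a
    Spearman correlation is computed within patient, Fisher z-transformed
    (|r| clipped just below 1 to keep z finite), and tested against zero
    with a one-sample t-test across patients.  Patients with constant
    durations are excluded with a warning count.
    """
    rs, excluded = [], 0
    for dur, power in per_patient:
        dur = np.asarray(dur, float)
        power = np.asarray(power, float)
        ok = np.isfinite(dur) & np.isfinite(power)
        if ok.sum() < 3 or np.ptp(dur[ok]) == 0 or np.ptp(power[ok]) == 0:
            excluded += 1
            continue
        r, _ = sps.spearmanr(dur[ok], power[ok])
        rs.append(np.clip(r, -_FISHER_CLIP, _FISHER_CLIP))
    if len(rs) < 3:
        raise ValueError("need at least 3 usable patients")
    zs = np.arctanh(rs)
    t, p = sps.ttest_1samp(zs, 0.0)
    return dict(mean_r=float(np.mean(rs)), t=float(t), p=float(p),
                df=len(zs) - 1, n_patients=len(zs), n_excluded=excluded,
                r_values=[float(r) for r in rs])


def event_contingency(spindles: pd.DataFrame, ripples: pd.DataFrame,
                      window_s: float = 1.0) -> dict:
    """Event co-occurrence rates between spindles and ripples.

    Returns the percentage of spindles whose onset lies within ±window_s
    of any ripple peak, and the percentage of ripples overlapped in time by
    any spindle.
    """
    if len(spindles) == 0 or len(ripples) == 0:
        return dict(pct_spindles_near_ripples=0.0, pct_ripples_with_spindle=0.0)
    onsets = np.asarray(spindles["onset_s"], float)
    peaks = np.asarray(ripples["peak_s"], float)
    near = np.abs(onsets[:, None] - peaks[None, :]) <= window_s
    pct_spindles = 100.0 * near.any(axis=1).mean()
    s0 = np.asarray(spindles["onset_s"], float)
    s1 = np.asarray(spindles["offset_s"], float)
    r0 = np.asarray(ripples["onset_s"], float)
    r1 = np.asarray(ripples["offset_s"], float)
    overlap = (r0[:, None] < s1[None, :]) & (s0[None, :] < r1[:, None])
    pct_ripples = 100.0 * overlap.any(axis=1).mean()
    return dict(pct_spindles_near_ripples=float(pct_spindles),
                pct_ripples_with_spindle=float(pct_ripples))
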