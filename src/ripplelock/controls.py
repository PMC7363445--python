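"""Matched ripple-free surrogate (control) events.

For every detected ripple, 100 surrogate intervals of identical duration
are drawn from artifact-free NREM sleep such that the surrogate span plus
1.5 s of padding on each side contains no detected ripple.  Candidate
centres are restricted to ±10 min around the ripple and weighted by a
truncated Gaussian (SD 200 s by default), so surrogates share the slow
non-stationarities of their ripple's neighbourhood.  Spans once assigned
are excluded from all later draws, keeping surrogates non-overlapping
across the 100 sets; if a ripple's window is exhausted it is widened in
5-minute steps (with a warning) while all other constraints are kept.

The 100 sets serve two purposes downstream: element-wise averaging for
paired power comparisons (each ripple paired with its mean control), and a
100-value null distribution for connectivity z-statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ControlParams:
    halfwindow_s: float = 600.0  # ±10 min candidate window
    gaussian_sd_s: float = 200.0
    n_sets: int = 100
    pad_s: float = 1.5  # ripple-free padding around each surrogate
    widen_step_s: float = 300.0  # window widening on exhaustion
    edge_margin_s: float = 3.0  # keep centres epochable (±3 s segments)
    seed: int = 0


@dataclass
class ControlEventSets:
    """Surrogate table with one row per (set, ripple)."""

    sets: pd.DataFrame  # columns: set_id, ripple_id, center_s, duration_s
    params: ControlParams = field(default_factory=ControlParams)

    def set_ids(self) -> np.ndarray:
        return np.sort(self.sets["set_id"].unique())

    def centers_of_set(self, set_id: int, ripple_order: np.ndarray | None = None
                       ) -> pd.DataFrame:
        sel = self.sets[self.sets["set_id"] == set_id]
        return sel.set_index("ripple_id")


def draw_control_sets(
    ripples: pd.DataFrame,
    clean_nrem: np.ndarray,
    fs: float,
    params: ControlParams = ControlParams(),
) -> ControlEventSets:
    """Draw ``params.n_sets`` duration-matched ripple-free surrogate sets.

    Parameters
    ----------
    ripples : event table with onset_s/offset_s/peak_s/duration_s/id
    clean_nrem : bool array, True where the sample is artifact-free NREM
    """
    if len(ripples) == 0:
        raise ValueError("ripple list is empty")
    n = len(clean_nrem)
    rng = np.random.default_rng(params.seed)

    # static forbidden track: outside clean NREM, or inside a detected
    # ripple interval (the 1.5 s pads are enforced via the window check)
    bad = (~np.asarray(clean_nrem, bool)).astype(np.int64)
    for r in ripples.itertuples():
        k0, k1 = int(r.onset_s * fs), int(np.ceil(r.offset_s * fs))
        bad[max(k0, 0): min(k1, n)] = 1
    cum_bad = np.concatenate([[0], np.cumsum(bad)])

    assigned: list[tuple[int, int]] = []  # sample intervals already used
    rows = []
    for set_id in range(params.n_sets):
        for r in ripples.itertuples():
            dur = float(r.duration_s)
            edge = int(np.ceil(params.edge_margin_s * fs))
            half = int(np.ceil((dur / 2 + params.pad_s) * fs))
            half_core = int(np.ceil(dur / 2 * fs))
            window = params.halfwindow_s
            placed = False
            widened = False
            while not placed:
                for _ in range(4000):
                    # truncated Gaussian offset from the ripple peak
                    off = rng.normal(0.0, params.gaussian_sd_s)
                    if abs(off) > window:
                        continue
                    c = int(round((r.peak_s + off) * fs))
                    if c - max(half, edge) < 0 or c + max(half, edge) >= n:
                        continue
                    if cum_bad[c + half] - cum_bad[c - half] > 0:
                        continue
                    if any(c - half_core < b1 and b0 < c + half_core
                           for b0, b1 in assigned):
                        continue
                    assigned.append((c - half_core, c + half_core))
                    rows.append(dict(set_id=set_id, ripple_id=int(r.id),
                                     center_s=c / fs, duration_s=dur))
                    placed = True
                    break
                if not placed:
                    window += params.widen_step_s
                    widened = True
                    if window > n / fs:
                        raise RuntimeError(
                            f"control-event space exhausted for ripple "
                            f"{r.id} in set {set_id}: no eligible "
                            f"duration-matched span remains")
            if widened:
                logger.warning(
                    "control window for ripple %s widened to ±%.0f s",
                    r.id, window)
    sets = pd.DataFrame(rows, columns=["set_id", "ripple_id", "center_s",
                                       "duration_s"])
    return ControlEventSets(sets=sets, params=params)


def audit_control_sets(
    controls: ControlEventSets,
    ripples: pd.DataFrame,
    clean_nrem: np.ndarray,
    fs: float,
) -> dict:
    """Exhaustively verify every constraint on every surrogate.

    Returns a dict of violation counts (all zero for a valid draw):
    duration mismatch, ripple overlap within the padded span, dirty or
    non-NREM samples in the padded span, centre outside the (possibly
    widened) window, and pairwise overlap across all sets.
    """
    pad = controls.params.pad_s
    by_id = ripples.set_index("id")
    n = len(clean_nrem)
    viol = dict(count=0, duration=0, ripple_overlap=0, not_clean_nrem=0,
                outside_window=0, overlap=0)
    rip_iv = [(float(t.onset_s), float(t.offset_s)) for t in ripples.itertuples()]
    expected = controls.params.n_sets * len(ripples)
    viol["count"] = int(len(controls.sets) != expected)

    spans = []
    for s in controls.sets.itertuples():
        rip = by_id.loc[s.ripple_id]
        if abs(s.duration_s - rip["duration_s"]) > 1e-9:
            viol["duration"] += 1
        a = s.center_s - s.duration_s / 2 - pad
        b = s.center_s + s.duration_s / 2 + pad
        if any(a < r1 and r0 < b for r0, r1 in rip_iv):
            viol["ripple_overlap"] += 1
        k0, k1 = max(int(a * fs), 0), min(int(np.ceil(b * fs)), n)
        if not clean_nrem[k0:k1].all():
            viol["not_clean_nrem"] += 1
        if abs(s.center_s - rip["peak_s"]) > controls.params.halfwindow_s + 1e-9:
            viol["outside_window"] += 1
        spans.append((s.center_s - s.duration_s / 2, s.center_s + s.duration_s / 2))

    spans.sort()
    for (a0, a1), (b0, b1) in zip(spans[:-1], spans[1:]):
        if b0 < a1 - 1e-12:
            viol["overlap"] += 1
    return viol


def average_control_epochs(tfr_per_set: np.ndarray) -> np.ndarray:
    """Element-wise mean over the control sets.

    ``tfr_per_set`` has the set axis first (n_sets, n_ripples, ...); the
    result is the per-ripple average control, aligned to its ripple for
    paired statistics.
    """
    arr = np.asarray(tfr_per_set)
    if arr.shape[0] == 0:
        raise ValueError("no control sets supplied")
    return np.nanmean(arr, axis=0)
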