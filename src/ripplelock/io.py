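"""Reading and writing of sleep-EEG recordings, hypnograms and event tables.

Two on-disk signal formats are supported: European Data Format (EDF, 16-bit)
and a plain float32 binary with a JSON sidecar header.  Hypnograms are plain
text, one stage label per 20 s scoring epoch.  Discrete events (spindles,
ripples) travel as TSV tables with a fixed header.

Conventions used throughout the package: time is seconds from recording
start, samples are 0-based, intervals are half-open ``[onset, offset)``,
amplitudes are microvolts.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

STAGES = ("W", "S1", "S2", "SWS", "REM", "unscored")
#: sleep stages treated as NREM for detection/thresholding (S1 excluded by
#: default; see :func:`nrem_mask`)
NREM_STAGES = ("S2", "SWS")

EVENT_COLUMNS = [
    "id",
    "channel",
    "kind",
    "onset_s",
    "offset_s",
    "peak_s",
    "duration_s",
    "peak_amp_uv",
]

SPINDLE_DUR_BOUNDS = (0.4, 3.0)
RIPPLE_DUR_BOUNDS = (0.038, 0.5)


class FormatError(ValueError):
    """Unsupported or malformed on-disk format."""


@dataclass
class Recording:
    """Multichannel continuous signal with channel roles.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
    channel_roles : dict
        Map channel name -> role, role in {"NC", "HIPP", "other"}.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    channel_roles: dict[str, str] = field(default_factory=dict)
    start_time: str | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} signal rows but "
                f"{len(self.channel_names)} channel names"
            )
        for name, role in self.channel_roles.items():
            if name not in self.channel_names:
                raise ValueError(f"role given for unknown channel {name!r}")
            if role not in ("NC", "HIPP", "other"):
                raise ValueError(f"unknown role {role!r}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name_or_role: str) -> np.ndarray:
        """Return one channel's samples by name or by role ("NC"/"HIPP")."""
        if name_or_role in self.channel_names:
            return self.data[self.channel_names.index(name_or_role)]
        for name, role in self.channel_roles.items():
            if role == name_or_role:
                return self.data[self.channel_names.index(name)]
        raise KeyError(
            f"no channel with name or role {name_or_role!r}; "
            f"have {self.channel_names} with roles {self.channel_roles}"
        )

    def role_channel_name(self, role: str) -> str:
        for name, r in self.channel_roles.items():
            if r == role:
                return name
        raise KeyError(f"no channel with role {role!r}")


@dataclass
class Hypnogram:
    """Sequence of sleep-stage labels, one per fixed-length scoring epoch."""

    stages: list[str]
    epoch_len_s: float = 20.0

    def __post_init__(self) -> None:
        bad = sorted(set(self.stages) - set(STAGES))
        if bad:
            raise ValueError(f"unknown stage labels {bad}; allowed: {STAGES}")
        if self.epoch_len_s <= 0:
            raise ValueError("epoch_len_s must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.stages) * self.epoch_len_s

    def stage_of_sample(self, sample: int, fs: float) -> str:
        idx = int(sample / (self.epoch_len_s * fs))
        if idx >= len(self.stages):
            idx = len(self.stages) - 1
        return self.stages[idx]

    def stage_vector(self, fs: float, n_samples: int) -> np.ndarray:
        """Per-sample stage labels (object array of str)."""
        spe = int(round(self.epoch_len_s * fs))
        vec = np.repeat(np.asarray(self.stages, dtype=object), spe)
        if len(vec) < n_samples:
            if n_samples - len(vec) > spe:
                raise ValueError(
                    "hypnogram shorter than recording by more than one epoch"
                )
            vec = np.concatenate([vec, np.repeat(vec[-1], n_samples - len(vec))])
        return vec[:n_samples]


def nrem_mask(
    hypnogram: Hypnogram,
    fs: float,
    n_samples: int,
    include_s1: bool = False,
) -> np.ndarray:
    """Boolean per-sample mask, True where the stage counts as NREM.

    NREM is S2+SWS by default.  S1 is excluded because its inclusion would
    contaminate the control pool with wake-adjacent activity; set
    ``include_s1=True`` to override.
    """
    stages = set(NREM_STAGES) | ({"S1"} if include_s1 else set())
    vec = hypnogram.stage_vector(fs, n_samples)
    return np.isin(vec, sorted(stages))


# ---------------------------------------------------------------------------
# Event tables


def make_event_list(rows: Iterable[dict] | pd.DataFrame) -> pd.DataFrame:
    """Build a validated event table (one row per spindle/ripple).

    Columns: id, channel, kind, onset_s, offset_s, peak_s, duration_s,
    peak_amp_uv.  Raises on inconsistent timing.
    """
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS) if not isinstance(
        rows, pd.DataFrame
    ) else rows.loc[:, EVENT_COLUMNS].copy()
    if len(df) == 0:
        return df
    df = df.reset_index(drop=True)
    if not ((df["onset_s"] < df["peak_s"] + 1e-9) & (df["peak_s"] <= df["offset_s"] + 1e-9)).all():
        raise ValueError("event rows must satisfy onset < peak <= offset")
    if not np.allclose(df["duration_s"], df["offset_s"] - df["onset_s"], atol=1e-6):
        raise ValueError("duration_s must equal offset_s - onset_s")
    return df


def empty_event_list() -> pd.DataFrame:
    return pd.DataFrame(columns=EVENT_COLUMNS)


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"event table {path} missing columns {sorted(missing)}")
    return make_event_list(df)


# ---------------------------------------------------------------------------
# Hypnogram text format (one stage per line)


def write_hypnogram(hyp: Hypnogram, path: str | Path) -> None:
    Path(path).write_text("\n".join(hyp.stages) + "\n")


def read_hypnogram(path: str | Path, epoch_len_s: float = 20.0) -> Hypnogram:
    stages = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    return Hypnogram(stages=stages, epoch_len_s=epoch_len_s)


# ---------------------------------------------------------------------------
# Signal formats

_ROLE_HINTS = {
    "NC": ("cz", "c3", "c4", "oz", "nc", "scalp"),
    "HIPP": ("hip", "hc", "depth"),
}


def guess_roles(channel_names: Sequence[str]) -> dict[str, str]:
    """Heuristic channel-name -> role map (NC/HIPP/other)."""
    roles: dict[str, str] = {}
    for name in channel_names:
        low = name.lower()
        role = "other"
        for r, hints in _ROLE_HINTS.items():
            if any(h in low for h in hints):
                role = r
                break
        roles[name] = role
    return roles


def _require_roles(rec: Recording, required: Sequence[str]) -> None:
    have = set(rec.channel_roles.values())
    missing = [r for r in required if r not in have]
    if missing:
        raise FormatError(
            f"recording is missing channels for required role(s) {missing}; "
            f"channels present: {rec.channel_names}"
        )


def write_recording(rec: Recording, path: str | Path, format: str = "edf") -> None:
    fmt = format.lower()
    if fmt == "edf":
        _write_edf(rec, Path(path))
    elif fmt == "raw":
        _write_raw(rec, Path(path))
    else:
        raise FormatError(f"unsupported format {format!r} (use 'edf' or 'raw')")


def read_recording(
    path: str | Path,
    format: str | None = None,
    channel_roles: dict[str, str] | None = None,
    require: Sequence[str] = (),
) -> Recording:
    """Read a recording from EDF or raw-binary+JSON-header.

    ``channel_roles`` overrides the name-based heuristics; ``require`` lists
    roles (e.g. ``["NC", "HIPP"]``) that must resolve or an error is raised.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "raw"
    fmt = format.lower()
    if fmt == "edf":
        rec = _read_edf(path)
    elif fmt == "raw":
        rec = _read_raw(path)
    else:
        raise FormatError(f"unsupported format {format!r} (use 'edf' or 'raw')")
    if channel_roles:
        rec.channel_roles = dict(channel_roles)
    elif not rec.channel_roles:
        rec.channel_roles = guess_roles(rec.channel_names)
    _require_roles(rec, require)
    return rec


def _write_raw(rec: Recording, path: Path) -> None:
    header = {
        "fs": rec.fs,
        "channel_names": rec.channel_names,
        "channel_roles": rec.channel_roles,
        "n_samples": rec.n_samples,
        "dtype": "float32",
        "units": "uV",
        "start_time": rec.start_time,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(header, indent=1))
    rec.data.astype("<f4").tofile(path)


def _read_raw(path: Path) -> Recording:
    hdr_path = path.with_suffix(path.suffix + ".json")
    if not hdr_path.exists():
        raise FormatError(f"missing JSON header {hdr_path}")
    hdr = json.loads(hdr_path.read_text())
    data = np.fromfile(path, dtype="<f4").astype(float)
    n_ch = len(hdr["channel_names"])
    data = data.reshape(n_ch, hdr["n_samples"])
    return Recording(
        data=data,
        fs=float(hdr["fs"]),
        channel_names=list(hdr["channel_names"]),
        channel_roles=dict(hdr.get("channel_roles") or {}),
        start_time=hdr.get("start_time"),
    )


# EDF: 256-byte fixed header, 256 bytes per signal, then data records of
# little-endian int16.  No installed library writes EDF, so the writer is
# implemented here; reading goes through MNE's native EDF reader.


def _edf_str(value: object, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(rec: Recording, path: Path) -> None:
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = rec.n_channels
    spr = fs  # one-second data records
    n_rec = int(np.ceil(rec.n_samples / spr))
    data = np.zeros((n_ch, n_rec * spr))
    data[:, : rec.n_samples] = rec.data

    # physical scaling chosen per channel, symmetric around zero; rounded
    # up to the header's 0.1 uV precision so reader and writer agree
    phys_max = np.ceil(np.maximum(np.abs(data).max(axis=1), 1.0) * 10) / 10
    dig_max, dig_min = 32767, -32768

    with open(path, "wb") as f:
        f.write(_edf_str("0", 8))
        f.write(_edf_str("X X X X", 80))  # local patient id (anonymous)
        f.write(_edf_str("Startdate X X X X", 80))
        f.write(_edf_str("01.01.00", 8))
        f.write(_edf_str("00.00.00", 8))
        f.write(_edf_str(256 * (1 + n_ch), 8))
        f.write(_edf_str("", 44))
        f.write(_edf_str(n_rec, 8))
        f.write(_edf_str(1, 8))  # record duration, seconds
        f.write(_edf_str(n_ch, 4))
        for name in rec.channel_names:
            f.write(_edf_str(name, 16))
        for name in rec.channel_names:
            role = rec.channel_roles.get(name, "other")
            f.write(_edf_str(f"EEG {role}", 80))
        for _ in range(n_ch):
            f.write(_edf_str("uV", 8))
        for ch in range(n_ch):
            f.write(_edf_str(f"{-phys_max[ch]:.1f}"[:8], 8))
        for ch in range(n_ch):
            f.write(_edf_str(f"{phys_max[ch]:.1f}"[:8], 8))
        for _ in range(n_ch):
            f.write(_edf_str(dig_min, 8))
        for _ in range(n_ch):
            f.write(_edf_str(dig_max, 8))
        for _ in range(n_ch):
            f.write(_edf_str("", 80))  # prefiltering
        for _ in range(n_ch):
            f.write(_edf_str(spr, 8))
        for _ in range(n_ch):
            f.write(_edf_str("", 32))

        scale = (dig_max - dig_min) / (2 * phys_max)
        for r in range(n_rec):
            for ch in range(n_ch):
                chunk = data[ch, r * spr : (r + 1) * spr]
                dig = np.round(chunk * scale[ch]).clip(dig_min, dig_max)
                f.write(dig.astype("<i2").tobytes())


def _read_edf(path: Path) -> Recording:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE loads EEG in volts
    names = list(raw.ch_names)
    return Recording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_names=names,
        channel_roles=guess_roles(names),
    )


# ---------------------------------------------------------------------------
# Interval TSV (artifact masks, control events) and JSON results


def write_intervals(intervals: Iterable[tuple], path: str | Path, columns: Sequence[str]) -> None:
    pd.DataFrame(list(intervals), columns=list(columns)).to_csv(
        path, sep="\t", index=False
    )


def write_json(obj: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=1, default=_default))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
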