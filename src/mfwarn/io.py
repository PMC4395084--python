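"""Recording, annotation and configuration I/O.

Signals travel as EDF (the ubiquitous EEG interchange format): a compact
16-bit writer lives here, and reading goes through MNE's EDF reader, which
also serves as an independent check that the written files are conformant.
Annotations and gaps are sidecar CSVs (``annotations.csv``: onset_s, type;
``gaps.csv``: start_s, end_s), run configuration is YAML, and detectors and
reports serialize to JSON.  All times are seconds from recording start.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, FormatError, ParameterError
from .recording import Recording

__all__ = [
    "RunConfig",
    "write_edf",
    "read_recording",
    "write_recording",
    "read_epochs_csv",
    "write_epochs_csv",
]


# --------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """All tunable constants of the pipeline, YAML round-trippable."""

    sampling_rate: float = 2000.0
    scales: tuple[int, int] = (3, 7)
    q_grid: list[float] | None = None
    R: int = 100
    sub_window_s: float = 2.0
    window_s: float = 60.0
    step_s: float = 15.0
    consecutive_windows: int = 5
    tau_grid_min: list[float] = field(
        default_factory=lambda: [5, 10, 15, 20, 25, 30, 35, 40, 45, 50, 55, 60]
    )
    critical_fpr_per_h: float = 0.15
    feature_set: str = "FS3"
    channels: list[str] | None = None
    seed: int = 0
    synth: dict | None = None

    def __post_init__(self) -> None:
        self.scales = tuple(int(j) for j in self.scales)
        dt = 1.0 / self.sampling_rate
        for name in ("sub_window_s", "window_s", "step_s"):
            w = getattr(self, name)
            if w <= 0 or abs(round(w / dt) - w / dt) > 1e-6:
                raise ConfigurationError(
                    f"{name}={w} must be a positive multiple of the sample period {dt}"
                )
        taus = list(self.tau_grid_min)
        if taus != sorted(taus):
            raise ConfigurationError("tau_grid_min must be sorted ascending")
        self.tau_grid_min = taus

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scales"] = list(self.scales)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# --------------------------------------------------------------------------
# EDF

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(path, recording: Recording) -> None:
    """Write a Recording as a 16-bit EDF file (1-second data records).

    The physical range is set per channel from the data, so the
    quantization step is range/65535.  The sampling rate must be an integer
    (samples per 1-s record); a trailing partial second is dropped.
    """
    fs = recording.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_rec = recording.n_samples // fs
    if n_rec < 1:
        raise FormatError("recording shorter than one EDF data record (1 s)")
    data = recording.samples[:, : n_rec * fs]
    ns = recording.n_channels
    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmax = np.where(flat, pmin + 1.0, pmax)

    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad("Startdate X X X X", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (ns + 1)), 8),
            _pad("", 44),
            _pad(str(n_rec), 8),
            _pad("1", 8),
            _pad(str(ns), 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_pad(lbl, 16) for lbl in recording.channel_labels),
            b"".join(_pad("", 80) for _ in range(ns)),
            b"".join(_pad("uV", 8) for _ in range(ns)),
            b"".join(_pad(f"{v:.6g}"[:8], 8) for v in pmin),
            b"".join(_pad(f"{v:.6g}"[:8], 8) for v in pmax),
            b"".join(_pad(str(_EDF_DIG_MIN), 8) for _ in range(ns)),
            b"".join(_pad(str(_EDF_DIG_MAX), 8) for _ in range(ns)),
            b"".join(_pad("", 80) for _ in range(ns)),
            b"".join(_pad(str(fs), 8) for _ in range(ns)),
            b"".join(_pad("", 32) for _ in range(ns)),
        ]
    )
    # re-read the physical extrema exactly as written, so scaling matches readers
    pmin_w = np.array([float(_pad(f"{v:.6g}"[:8], 8)) for v in pmin])
    pmax_w = np.array([float(_pad(f"{v:.6g}"[:8], 8)) for v in pmax])
    pmax_w = np.where(pmax_w - pmin_w < 1e-12, pmin_w + 1.0, pmax_w)
    scale = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (pmax_w - pmin_w)
    dig = np.clip(
        np.rint((data - pmin_w[:, None]) * scale[:, None]) + _EDF_DIG_MIN,
        _EDF_DIG_MIN,
        _EDF_DIG_MAX,
    ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        # records: for each second, all channels' samples consecutively
        blocks = dig.reshape(ns, n_rec, fs).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(blocks).tobytes())


def _read_gaps_csv(path) -> list[tuple[float, float]]:
    df = pd.read_csv(path)
    return [(float(a), float(b)) for a, b in zip(df["start_s"], df["end_s"])]


def _read_annotations_csv(path) -> list[float]:
    df = pd.read_csv(path)
    sel = df if "type" not in df else df[df["type"].astype(str) == "seizure_onset"]
    return [float(t) for t in sel["onset_s"]]


def read_recording(
    path,
    montage: dict[str, tuple[str, str]] | None = None,
    gaps_csv=None,
    annotations_csv=None,
    split_tag: str = "testing",
) -> Recording:
    """Read an EDF into a Recording (microvolts), with optional bipolar montage.

    ``montage`` maps derived labels to referential channel pairs, e.g.
    ``{"A1-A2": ("A1", "A2")}`` producing the pointwise difference.  Gaps and
    seizure annotations are read from sidecar CSVs; conventionally named
    sidecars (``gaps.csv``, ``annotations.csv`` next to the EDF) are picked
    up automatically, and a missing sidecar yields an empty list.
    """
    import mne

    path = Path(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    sfreqs = {raw.info["sfreq"]}
    if len(sfreqs) != 1:
        raise FormatError(f"inconsistent sampling rates in {path}: {sfreqs}")
    data_uv = raw.get_data() * 1e6
    labels = list(raw.ch_names)
    if montage:
        derived, dlabels = [], []
        for lbl, (ref_a, ref_b) in montage.items():
            for ref in (ref_a, ref_b):
                if ref not in labels:
                    raise ConfigurationError(f"unknown channel {ref!r} in montage")
            derived.append(data_uv[labels.index(ref_a)] - data_uv[labels.index(ref_b)])
            dlabels.append(lbl)
        data_uv, labels = np.asarray(derived), dlabels
    if gaps_csv is None and (path.parent / "gaps.csv").exists():
        gaps_csv = path.parent / "gaps.csv"
    if annotations_csv is None and (path.parent / "annotations.csv").exists():
        annotations_csv = path.parent / "annotations.csv"
    gaps = _read_gaps_csv(gaps_csv) if gaps_csv else []
    onsets = _read_annotations_csv(annotations_csv) if annotations_csv else []
    return Recording(
        samples=data_uv,
        sampling_rate=float(raw.info["sfreq"]),
        channel_labels=labels,
        gaps=gaps,
        seizure_onsets=onsets,
        split_tag=split_tag,
    )


def write_recording(outdir, recording: Recording, stem: str = "recording") -> Path:
    """Write EDF plus annotations.csv / gaps.csv sidecars; returns the EDF path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    edf = outdir / f"{stem}.edf"
    write_edf(edf, recording)
    pd.DataFrame(
        {"onset_s": recording.seizure_onsets, "type": "seizure_onset"}
    ).to_csv(outdir / "annotations.csv", index=False)
    pd.DataFrame(
        recording.gaps or [], columns=["start_s", "end_s"]
    ).to_csv(outdir / "gaps.csv", index=False)
    return edf


# --------------------------------------------------------------------------
# epochs and tables


def read_epochs_csv(path):
    from .discriminability import Epoch

    df = pd.read_csv(path)
    return [Epoch(float(r.start_s), float(r.end_s), str(r.label)) for r in df.itertuples()]


def write_epochs_csv(path, epochs) -> None:
    pd.DataFrame(
        [{"start_s": e.start, "end_s": e.end, "label": e.label} for e in epochs]
    ).to_csv(path, index=False)


def features_to_frame(series, bands=None) -> pd.DataFrame:
    """Tidy (channel, window_start_s, c1, c2, band powers, valid) table."""
    rows = []
    for i, ch in enumerate(series.channel_labels):
        df = pd.DataFrame(
            {
                "channel": ch,
                "window_start_s": series.window_starts,
                "c1": series.c1[i],
                "c2": series.c2[i],
                "valid": series.valid[i],
            }
        )
        if bands is not None:
            for name, arr in bands.powers.items():
                df[name] = arr[i]
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def frame_to_features(df: pd.DataFrame):
    """Inverse of :func:`features_to_frame` (cumulant columns only)."""
    from .features import CumulantSeries

    channels = list(dict.fromkeys(df["channel"]))
    starts = np.sort(np.unique(df["window_start_s"].to_numpy(float)))
    shape = (len(channels), starts.size)
    c1 = np.full(shape, np.nan)
    c2 = np.full(shape, np.nan)
    valid = np.zeros(shape, bool)
    pos = {t: i for i, t in enumerate(starts)}
    for i, ch in enumerate(channels):
        sub = df[df["channel"] == ch]
        idx = [pos[t] for t in sub["window_start_s"].to_numpy(float)]
        c1[i, idx] = sub["c1"]
        c2[i, idx] = sub["c2"]
        valid[i, idx] = sub["valid"].astype(bool)
    step = float(np.min(np.diff(starts))) if starts.size > 1 else 15.0
    return CumulantSeries(
        window_starts=starts, c1=c1, c2=c2, valid=valid,
        channel_labels=channels, step=step,
    )


def save_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def load_json(path):
    return json.loads(Path(path).read_text())
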