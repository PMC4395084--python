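"""Sliding-window feature series: log-cumulants and spectral band powers.

Per channel, (c1, c2) are estimated on consecutive non-overlapping 2-s
windows (bootstrap wavelet-leader estimates over a dyadic scale range,
default octaves 3–7) and then averaged inside 1-min windows advanced on a
15-s grid — the grid every later stage (epoch averaging, classification,
warning protocol) lives on.  Spectral band powers are computed on the same
1-min/15-s grid via Welch periodograms for the conventional EEG bands up to
fast ripples.

Validity propagation: a 2-s window intersecting a recording gap, or one
whose leader pyramid degenerates, is invalid; a 1-min window is invalid if
it intersects a gap at all, or if more than half of its 2-s sub-windows are
invalid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from ._seeding import spawn_generators
from .exceptions import ParameterError
from .leaders import bootstrap_cumulants, compute_leaders, dwt_pyramid
from .recording import Recording

__all__ = [
    "EEG_BANDS",
    "CumulantSeries",
    "BandPowerSeries",
    "window_grid",
    "cumulant_series",
    "band_power_series",
    "scale_to_frequency",
    "fit_spectral_exponent",
]

#: conventional EEG frequency bands, Hz (half-open in spirit; edges as listed)
EEG_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 3.9),
    "theta": (4.0, 7.9),
    "alpha": (8.0, 14.0),
    "beta": (15.0, 30.0),
    "gamma": (30.0, 58.0),
    "ripples": (80.0, 250.0),
    "fast_ripples": (250.0, 450.0),
}


def window_grid(duration: float, length: float = 60.0, step: float = 15.0) -> np.ndarray:
    """Start times of full sliding windows: floor((D - length)/step) + 1 of them."""
    if duration < length:
        return np.empty(0)
    n = int(np.floor((duration - length) / step)) + 1
    return np.arange(n) * step


@dataclass
class CumulantSeries:
    """Per-channel c1/c2 averages on the 1-min / 15-s sliding grid."""

    window_starts: np.ndarray  # seconds, 15-s grid
    c1: np.ndarray  # (n_channels, n_windows)
    c2: np.ndarray
    valid: np.ndarray  # bool, same shape
    channel_labels: list[str]
    window_length: float = 60.0
    step: float = 15.0
    provenance: dict = field(default_factory=dict)
    #: externally supplied extra feature columns, name -> (n_channels, n_windows)
    extras: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.c1.shape[0]

    def feature_names(self) -> list[str]:
        return ["c1", "c2", *self.extras]

    def feature(self, name: str) -> np.ndarray:
        if name == "c1":
            return self.c1
        if name == "c2":
            return self.c2
        return self.extras[name]


@dataclass
class BandPowerSeries:
    """Mean spectral power (microvolt^2) per EEG band on the same sliding grid."""

    window_starts: np.ndarray
    powers: dict[str, np.ndarray]  # band -> (n_channels, n_windows)
    valid: np.ndarray
    channel_labels: list[str]
    window_length: float = 60.0
    step: float = 15.0

    def feature_names(self) -> list[str]:
        return list(self.powers)

    def feature(self, name: str) -> np.ndarray:
        return self.powers[name]


def _gap_free(starts: np.ndarray, length: float, gaps) -> np.ndarray:
    ok = np.ones(starts.size, bool)
    for a, b in gaps:
        ok &= ~((starts < b) & (a < starts + length))
    return ok


def _aggregate(
    starts: np.ndarray,
    sub_values: np.ndarray,
    sub_valid: np.ndarray,
    sub_length: float,
    length: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Average 2-s sub-window values inside each 1-min window (valid subs only)."""
    out = np.full(starts.shape, np.nan)
    ok = np.zeros(starts.shape, bool)
    vals = np.where(sub_valid, sub_values, 0.0)
    for i, t in enumerate(starts):
        k0 = int(np.ceil(t / sub_length))
        k1 = int(np.floor((t + length) / sub_length))  # exclusive
        total = k1 - k0
        nval = int(sub_valid[k0:k1].sum())
        if total > 0 and nval > total / 2:
            out[i] = vals[k0:k1].sum() / nval
            ok[i] = True
    return out, ok


def cumulant_series(
    recording: Recording,
    scales: tuple[int, int] = (3, 7),
    q_grid=None,
    R: int = 100,
    seed=None,
    sub_window: float = 2.0,
    window_length: float = 60.0,
    step: float = 15.0,
) -> CumulantSeries:
    """Sliding-window bootstrap log-cumulants for every channel of a recording.

    Raises a scale-feasibility error (from the pyramid) if ``sub_window``
    seconds at the recording's sampling rate cannot support octave
    ``scales[1]``.
    """
    j1, j2 = scales
    fs = recording.sampling_rate
    w = int(round(sub_window * fs))
    n_sub = recording.n_samples // w
    starts = window_grid(recording.duration, window_length, step)
    sub_starts = np.arange(n_sub) * sub_window
    gap_ok = _gap_free(sub_starts, sub_window, recording.gaps)
    c1 = np.full((recording.n_channels, starts.size), np.nan)
    c2 = np.full_like(c1, np.nan)
    valid = np.zeros(c1.shape, bool)
    child_rngs = spawn_generators(seed, recording.n_channels)
    for ch in range(recording.n_channels):
        batch = recording.samples[ch, : n_sub * w].reshape(n_sub, w)
        pyr = compute_leaders(dwt_pyramid(batch, j2, sampling_rate=fs))
        est = bootstrap_cumulants(pyr, j1, j2, R=R, seed=child_rngs[ch], q_grid=q_grid)
        sub_ok = est.valid & gap_ok
        c1[ch], ok1 = _aggregate(starts, est.c1, sub_ok, sub_window, window_length)
        c2[ch], _ = _aggregate(starts, est.c2, sub_ok, sub_window, window_length)
        valid[ch] = ok1 & _gap_free(starts, window_length, recording.gaps)
    c1[~valid] = np.nan
    c2[~valid] = np.nan
    return CumulantSeries(
        window_starts=starts,
        c1=c1,
        c2=c2,
        valid=valid,
        channel_labels=list(recording.channel_labels),
        window_length=window_length,
        step=step,
        provenance={"scales": [j1, j2], "R": R, "sub_window_s": sub_window,
                    "q_grid": None if q_grid is None else list(np.asarray(q_grid))},
    )


def band_power_series(
    recording: Recording,
    bands: dict[str, tuple[float, float]] | None = None,
    window_length: float = 60.0,
    step: float = 15.0,
    segment: float = 2.0,
) -> BandPowerSeries:
    """Welch band powers per 1-min window (2-s Hann segments, 50% overlap)."""
    bands = dict(bands or EEG_BANDS)
    fs = recording.sampling_rate
    nyq = fs / 2.0
    for name, (lo, hi) in bands.items():
        if hi >= nyq:
            raise ParameterError(f"band {name} upper edge {hi} Hz >= Nyquist {nyq} Hz")
        if lo >= hi:
            raise ParameterError(f"band {name} has empty range [{lo}, {hi}]")
    starts = window_grid(recording.duration, window_length, step)
    wlen = int(round(window_length * fs))
    stepn = int(round(step * fs))
    nper = int(round(segment * fs))
    powers = {name: np.full((recording.n_channels, starts.size), np.nan) for name in bands}
    valid = np.zeros((recording.n_channels, starts.size), bool)
    gap_ok = _gap_free(starts, window_length, recording.gaps)
    for ch in range(recording.n_channels):
        windows = np.lib.stride_tricks.sliding_window_view(recording.samples[ch], wlen)[
            ::stepn
        ][: starts.size]
        f, psd = sps.welch(
            windows, fs=fs, window="hann", nperseg=nper, noverlap=nper // 2, axis=-1
        )
        df = f[1] - f[0]
        for name, (lo, hi) in bands.items():
            sel = (f >= lo) & (f <= hi)
            powers[name][ch] = psd[:, sel].sum(axis=-1) * df
        valid[ch] = gap_ok
    for name in powers:
        powers[name][~valid] = np.nan
    return BandPowerSeries(
        window_starts=starts,
        powers=powers,
        valid=valid,
        channel_labels=list(recording.channel_labels),
        window_length=window_length,
        step=step,
    )


def scale_to_frequency(j: int, sampling_rate: float) -> float:
    """Representative frequency of octave ``j``: midpoint of [fs/2^(j+1), fs/2^j].

    Equals ``3 fs / 2^(j+2)``; e.g. octave 3 at 2000 Hz -> 187.5 Hz.
    """
    if j < 1:
        raise ParameterError("octave j must be >= 1")
    return 3.0 * sampling_rate / 2.0 ** (j + 2)


def fit_spectral_exponent(
    signal: np.ndarray | None = None,
    sampling_rate: float | None = None,
    f_range: tuple[float, float] = (1.0, 100.0),
    spectrum: tuple[np.ndarray, np.ndarray] | None = None,
    nperseg: int = 8192,
) -> tuple[float, float]:
    """Fit the 1/f^alpha power law; return (alpha, implied Hurst exponent).

    ``alpha`` is the negative slope of the OLS fit of log power against log
    frequency over ``f_range``; the implied Hurst exponent follows from
    ``alpha = 2H - 1`` for the stationary increment process.  Either a raw
    ``signal`` (Welch periodogram) or a precomputed ``spectrum = (f, P)``
    may be supplied.
    """
    if spectrum is not None:
        f, p = np.asarray(spectrum[0], float), np.asarray(spectrum[1], float)
    else:
        if signal is None or sampling_rate is None:
            raise ParameterError("provide either a signal with sampling_rate or a spectrum")
        lo, hi = f_range
        if not (0 < lo < hi <= sampling_rate / 2):
            raise ParameterError(f"f_range {f_range} outside (0, Nyquist]")
        f, p = sps.welch(
            np.asarray(signal, float),
            fs=sampling_rate,
            nperseg=min(len(signal), nperseg),
        )
    sel = (f >= f_range[0]) & (f <= f_range[1]) & (f > 0) & (p > 0)
    if sel.sum() < 2:
        raise ParameterError("no (or a single) frequency bin inside f_range")
    slope = np.polyfit(np.log10(f[sel]), np.log10(p[sel]), 1)[0]
    alpha = -slope
    return float(alpha), float((alpha + 1.0) / 2.0)
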