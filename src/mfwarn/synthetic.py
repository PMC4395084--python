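"""Synthetic scale-invariant signals and full synthetic patients.

Every downstream stage of the pipeline (leader pyramid, cumulant features,
discriminant training, warning protocol, evaluation) is testable without any
EEG download by generating signals whose scaling properties are known in
closed form:

* fractional Brownian motion (fBm) — the canonical monofractal,
  self-similar process with Hurst exponent ``H``; its log-cumulants are
  ``c1 = H`` and ``c2 = 0``;
* the multifractal random walk (MRW) — Gaussian noise modulated by the
  exponential of a log-correlated Gaussian multiplier with variance
  parameter ``lambda² = intermittency``; its second log-cumulant is
  ``c2 = -lambda²``;
* synthetic "patients" — multichannel 1/f-like recordings with interictal
  background, preictal segments whose first cumulant is shifted on selected
  channels, seizure-onset annotations and recording gaps.

Fractional Gaussian noise is synthesised by exact circulant embedding of its
covariance (Davies–Harte), so recovery tests downstream measure estimator
error only, not simulator bias.  All randomness flows from a single
``numpy.random.Generator`` seeded per call; there is no global state.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import fft as sfft

from ._seeding import as_generator
from .exceptions import ParameterError
from .recording import Recording

__all__ = [
    "ScalingGroundTruth",
    "simulate_fgn",
    "simulate_fbm",
    "simulate_mrw",
    "simulate_recording",
]


@dataclass(frozen=True)
class ScalingGroundTruth:
    """True scaling parameters of a simulated signal.

    ``hurst`` is the self-similarity exponent H in (0, 1); ``intermittency``
    is the variance lambda² of the log-multiplier of an MRW (0 for a
    monofractal).  The implied log-cumulants and the 1/f spectral exponent
    of the increment process (alpha = 2H - 1) are derived fields.
    """

    hurst: float
    intermittency: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.hurst < 1.0:
            raise ParameterError(f"hurst must lie in (0, 1), got {self.hurst}")
        if self.intermittency < 0:
            raise ParameterError("intermittency (lambda^2) must be >= 0")

    @property
    def expected_c1(self) -> float:
        return self.hurst + self.intermittency

    @property
    def expected_c2(self) -> float:
        return -self.intermittency

    @property
    def spectral_alpha(self) -> float:
        """Exponent of the 1/f^alpha law of the increment process."""
        return 2.0 * self.hurst - 1.0


def _fgn_autocovariance(hurst: float, n: int) -> np.ndarray:
    """Autocovariance gamma(0..n) of unit-variance fractional Gaussian noise."""
    k = np.arange(n + 1, dtype=float)
    h2 = 2.0 * hurst
    return 0.5 * ((k + 1.0) ** h2 - 2.0 * k**h2 + np.abs(k - 1.0) ** h2)


def _circulant_eigenvalues(gamma: np.ndarray) -> np.ndarray:
    """Eigenvalues (half spectrum) of the 2n-circulant embedding of gamma(0..n)."""
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = sfft.rfft(row).real
    # fGn embeddings are provably nonnegative definite; log-correlated
    # covariances can produce tiny negative eigenvalues — clip them.
    return np.clip(lam, 0.0, None)


@lru_cache(maxsize=16)
def _cached_sqrt_eigenvalues(kind: str, param: float, n: int, cutoff: int) -> np.ndarray:
    if kind == "fgn":
        gamma = _fgn_autocovariance(param, n)
    else:  # "logmul"
        gamma = _log_multiplier_autocov(param, n, cutoff)
    return np.sqrt(_circulant_eigenvalues(gamma))


def _sample_circulant(sqrt_lam_half: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Stationary Gaussian series of length n from half-spectrum sqrt-eigenvalues.

    Hermitian half-spectrum sampling: one real inverse FFT of length 2n
    yields a sample with exactly the embedded circulant covariance.
    """
    m = 2 * n
    half = sqrt_lam_half.size  # n + 1
    z = rng.standard_normal(half) + 1j * rng.standard_normal(half)
    z[0] = np.sqrt(2.0) * z[0].real
    z[-1] = np.sqrt(2.0) * z[-1].real
    spec = sqrt_lam_half * z * np.sqrt(m / 2.0)
    return sfft.irfft(spec, n=m)[:n]


def _gaussian_from_autocov(gamma: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw a stationary Gaussian series of length n with autocovariance gamma."""
    return _sample_circulant(np.sqrt(_circulant_eigenvalues(gamma)), n, rng)


def simulate_fgn(hurst: float, n: int, seed=None) -> np.ndarray:
    """Fractional Gaussian noise of length ``n`` (unit variance), exact covariance."""
    if not 0.0 < hurst < 1.0:
        raise ParameterError(f"hurst must lie in (0, 1), got {hurst}")
    if n < 2:
        raise ParameterError("n must be >= 2")
    rng = as_generator(seed)
    return _sample_circulant(_cached_sqrt_eigenvalues("fgn", float(hurst), n, 0), n, rng)


def simulate_fbm(hurst: float, n: int, seed=None) -> np.ndarray:
    """One realization of fractional Brownian motion with Hurst exponent ``hurst``.

    The path is the cumulative sum of exact fractional Gaussian noise;
    deterministic for a fixed ``seed``.
    """
    return np.cumsum(simulate_fgn(hurst, n, seed))


def _log_multiplier_autocov(intermittency: float, n: int, cutoff: int) -> np.ndarray:
    """Log-correlated covariance lambda^2 * ln(L/(k+1)) for k < L, else 0."""
    k = np.arange(n + 1, dtype=float)
    g = intermittency * np.log(cutoff / (k + 1.0))
    return np.clip(g, 0.0, None)


def simulate_mrw(
    hurst: float,
    intermittency: float,
    n: int,
    seed=None,
    cutoff: int | None = None,
) -> np.ndarray:
    """One realization of a multifractal random walk.

    Increments are fractional Gaussian noise with exponent ``hurst``
    modulated by ``exp(omega)`` where ``omega`` is Gaussian with the
    logarithmic covariance ``lambda^2 ln(L / (lag+1))`` up to the integral
    scale ``L = cutoff`` (default: ``n``).  The walk's log-cumulants satisfy
    ``c2 = -intermittency``; ``intermittency = 0`` degenerates exactly to
    fractional Brownian motion.
    """
    if intermittency < 0:
        raise ParameterError("intermittency (lambda^2) must be >= 0")
    if cutoff is None:
        cutoff = n
    if cutoff > n:
        raise ParameterError("correlation cutoff scale must be <= n")
    rng = as_generator(seed)
    return np.cumsum(_mrw_increments(hurst, intermittency, n, rng, cutoff))


def _mrw_increments(
    hurst: float,
    intermittency: float,
    n: int,
    rng: np.random.Generator,
    cutoff: int | None = None,
) -> np.ndarray:
    eps = simulate_fgn(hurst, n, rng)
    if intermittency == 0.0:
        return eps
    cutoff = n if cutoff is None else cutoff
    omega = _sample_circulant(
        _cached_sqrt_eigenvalues("logmul", float(intermittency), n, cutoff), n, rng
    )
    # Center the multiplier so its exponential has unit median; constants do
    # not affect scaling exponents, only the signal amplitude.
    return eps * np.exp(omega - omega.mean())


def _validate_patient_args(
    duration: float,
    seizure_times: list[float],
    preictal_duration: float,
    gap_spec: list[tuple[float, float]],
) -> None:
    times = sorted(seizure_times)
    for t in times:
        if not 0 < t <= duration:
            raise ParameterError(f"seizure time {t} outside (0, {duration}]")
    for t0, t1 in zip(times, times[1:]):
        if t1 - t0 < preictal_duration:
            raise ParameterError(
                f"seizures at {t0} and {t1} closer than the preictal duration: "
                "preictal intervals would overlap"
            )
    for a, b in gap_spec:
        for t in times:
            if a <= t < b:
                raise ParameterError(f"gap [{a}, {b}) overlaps seizure onset at {t}")


def simulate_recording(
    n_channels: int,
    duration: float,
    sampling_rate: float = 2000.0,
    seizure_times: list[float] | None = None,
    preictal_duration: float = 300.0,
    c1_shift: float = 0.0,
    affected_channels: list[int] | None = None,
    gap_spec: list[tuple[float, float]] | None = None,
    seed=None,
    hurst: float = 0.6,
    intermittency: float = 0.02,
    amplitude: float = 20.0,
    crossfade: float = 2.0,
    max_segment: float = 900.0,
    c1_shift_mode: str = "hurst",
    normalize_variance: bool = True,
    multiplier_cutoff_s: float | None = None,
    split_tag: str = "testing",
) -> Recording:
    """Generate a full synthetic multichannel "patient" recording.

    The background of every channel is an MRW-type 1/f process with
    parameters ``(hurst, intermittency)``.  On ``affected_channels``, the
    windows inside ``[onset - preictal_duration, onset)`` are generated with
    the first log-cumulant shifted by ``c1_shift`` — either by shifting the
    Hurst exponent (``c1_shift_mode="hurst"``, which also tilts the 1/f
    spectrum) or by shifting the intermittency (``"intermittency"``, since
    c1 = H + lambda^2, which leaves the spectral shape of the Gaussian
    factor untouched — useful when the shift must not be visible in band
    powers).  Segments are stitched with a ``crossfade``-second linear
    crossfade of the increments to avoid splice artifacts.
    ``normalize_variance`` rescales each segment's increments to unit sample
    variance so regime changes do not change total power.  Gaps zero out the
    data and are recorded in ``gaps``; ``amplitude`` scales the increment
    standard deviation (microvolts).
    """
    if c1_shift_mode not in ("hurst", "intermittency"):
        raise ParameterError(f"unknown c1_shift_mode {c1_shift_mode!r}")
    seizure_times = sorted(seizure_times or [])
    gap_spec = sorted(tuple(map(float, g)) for g in (gap_spec or []))
    affected = sorted(set(affected_channels or []))
    if any(c < 0 or c >= n_channels for c in affected):
        raise ParameterError("affected_channels must be a subset of the channel indices")
    _validate_patient_args(duration, seizure_times, preictal_duration, gap_spec)

    n = int(round(duration * sampling_rate))
    nxf = int(round(crossfade * sampling_rate))
    rng = np.random.default_rng(seed)
    samples = np.empty((n_channels, n))

    base = (hurst, intermittency)
    if c1_shift_mode == "hurst":
        shifted = (hurst + c1_shift, intermittency)
    else:
        shifted = (hurst, intermittency + c1_shift)
    for h, lam2 in (base, shifted):
        if not 0.0 < h < 1.0:
            raise ParameterError(f"Hurst exponent {h} outside (0, 1); reduce c1_shift")
        if lam2 < 0.0:
            raise ParameterError(f"intermittency {lam2} negative; reduce c1_shift")

    for ch in range(n_channels):
        # Regime boundaries in samples: preictal intervals on affected channels.
        bounds: list[tuple[int, int, tuple]] = []  # (start, end, (hurst, lam2))
        cursor = 0
        if ch in affected and c1_shift != 0.0:
            for t in seizure_times:
                p0 = max(0, int(round((t - preictal_duration) * sampling_rate)))
                p1 = min(n, int(round(t * sampling_rate)))
                if p0 > cursor:
                    bounds.append((cursor, p0, base))
                bounds.append((p0, p1, shifted))
                cursor = p1
        if cursor < n:
            bounds.append((cursor, n, base))
        # Cap segment length so circulant FFTs stay small.
        cap = int(round(max_segment * sampling_rate))
        segments: list[tuple[int, int, tuple]] = []
        for a, b, params in bounds:
            while b - a > cap:
                segments.append((a, a + cap, params))
                a += cap
            segments.append((a, b, params))

        incr = np.empty(n)
        for i, (a, b, (h, lam2)) in enumerate(segments):
            head = min(nxf, a) if i > 0 else 0
            m = (b - a) + head
            cut = m if multiplier_cutoff_s is None else min(
                m, max(2, int(round(multiplier_cutoff_s * sampling_rate)))
            )
            seg = _mrw_increments(h, lam2, m, rng, cutoff=cut)
            if normalize_variance:
                seg = seg / max(seg.std(), 1e-30)
            if head:
                w = np.linspace(0.0, 1.0, head, endpoint=False)
                incr[a - head : a] = (1.0 - w) * incr[a - head : a] + w * seg[:head]
            incr[a:b] = seg[head:]
        samples[ch] = np.cumsum(incr) * amplitude

    for a, b in gap_spec:
        i0, i1 = int(round(a * sampling_rate)), min(n, int(round(b * sampling_rate)))
        samples[:, i0:i1] = 0.0

    labels = [f"SYN{ch + 1}-{ch + 2}" for ch in range(n_channels)]
    return Recording(
        samples=samples,
        sampling_rate=sampling_rate,
        channel_labels=labels,
        gaps=list(gap_spec),
        seizure_onsets=seizure_times,
        split_tag=split_tag,
    )
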