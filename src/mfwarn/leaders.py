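"""Wavelet-leader multifractal analysis: pyramid, structure functions, log-cumulants.

The multiresolution quantity is the *wavelet leader*: at octave ``j`` and
position ``k``, the supremum of discrete wavelet coefficient magnitudes over
all dyadic intervals at octaves ``j' <= j`` contained in the three-interval
time neighborhood of the dyadic interval ``lambda_{j,k}``.  Structure
functions (time averages of the q-th power of leaders) decay as ``2^{j
zeta(q)}`` across octaves; ``zeta(q)`` is expanded in log-cumulants
``zeta(q) = sum_p c_p q^p / p!``, estimated from the per-scale mean and
variance of ``ln L(j, .)`` by linear regression against ``j ln 2``.

Conventions (see docs/methods.md):

* detail coefficients are L1-normalized (raw dyadic-cascade outputs divided
  by ``2^{j/2}``) so that ``c1`` is directly comparable to the Hurst
  exponent of a self-similar input;
* the leader supremum includes the scale's own coefficients (``j' = j``);
* coefficients whose filter support touches the signal edge are flagged
  invalid and never enter leaders or statistics — no signal extension;
* regressions are unweighted ordinary least squares by default; weighting
  by the per-scale leader count is available but off by default.

All operations accept arrays with arbitrary leading (batch) axes; the last
axis is time.  This is what makes sliding-window feature extraction over
hours of signal a handful of vectorized calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .exceptions import ParameterError, ScaleFeasibilityError, StructuralError

__all__ = [
    "LeaderPyramid",
    "StructureFunctions",
    "ScalingEstimate",
    "dwt_pyramid",
    "compute_leaders",
    "structure_functions",
    "zeta_estimates",
    "log_cumulants",
    "bootstrap_cumulants",
]

#: leaders smaller than this multiple of the per-window median leader are
#: treated as numerically zero
TINY_LEADER_FACTOR = 1e-14

#: minimum number of valid leaders a scale must retain for a cumulant estimate
MIN_LEADERS_PER_SCALE = 8


def _analysis_filters(wavelet: str) -> tuple[np.ndarray, np.ndarray]:
    w = pywt.Wavelet(wavelet)
    return np.asarray(w.dec_lo)[::-1].copy(), np.asarray(w.dec_hi)[::-1].copy()


@dataclass
class LeaderPyramid:
    """Per-octave detail coefficients and wavelet leaders on the dyadic grid.

    ``coefficients[j-1]`` has shape ``(..., n_j)`` with ``n_j`` halving per
    octave; boolean masks flag boundary-affected positions invalid.
    ``leaders`` is filled by :func:`compute_leaders`.
    """

    coefficients: list[np.ndarray]
    coefficient_valid: list[np.ndarray]
    wavelet: str = "db3"
    sampling_rate: float | None = None
    leaders: list[np.ndarray] | None = None
    leader_valid: list[np.ndarray] | None = None

    @property
    def max_scale(self) -> int:
        return len(self.coefficients)

    @property
    def n_per_scale(self) -> list[int]:
        """Count of valid (non-boundary) leaders (or coefficients) per octave."""
        masks = self.leader_valid if self.leader_valid is not None else self.coefficient_valid
        return [int(np.min(m.sum(axis=-1))) for m in masks]


def _analysis_step(
    a: np.ndarray, valid: np.ndarray, filt: np.ndarray, n_out: int
) -> tuple[np.ndarray, np.ndarray]:
    """One filter-and-decimate step: out[k] = sum_i filt[i] a[..., 2k+i]."""
    L = filt.size
    need = 2 * (n_out - 1) + L
    pad = need - a.shape[-1]
    if pad > 0:
        a = np.concatenate([a, np.zeros(a.shape[:-1] + (pad,))], axis=-1)
        valid = np.concatenate([valid, np.zeros(valid.shape[:-1] + (pad,), bool)], axis=-1)
    out = np.zeros(a.shape[:-1] + (n_out,))
    vout = np.ones(valid.shape[:-1] + (n_out,), bool)
    for i in range(L):
        sl = a[..., i : i + 2 * n_out : 2]
        out += filt[i] * sl
        vout &= valid[..., i : i + 2 * n_out : 2]
    return out, vout


def dwt_pyramid(
    signal: np.ndarray,
    max_scale: int,
    wavelet: str = "db3",
    sampling_rate: float | None = None,
) -> LeaderPyramid:
    """Dyadic wavelet decomposition of ``signal`` up to octave ``max_scale``.

    Detail coefficients are returned in the L1-normalized convention (they
    scale as ``2^{jH}`` for an H-self-similar input).  At octave ``j`` there
    are ``floor(n / 2^j)`` coefficients; those whose filter support extends
    past the signal end are flagged invalid.
    """
    signal = np.asarray(signal, dtype=float)
    n = signal.shape[-1]
    filt_lo, filt_hi = _analysis_filters(wavelet)
    support = filt_lo.size
    if max_scale < 1:
        raise ParameterError("max_scale must be >= 1")
    if n < support * 2**max_scale:
        feasible = int(np.floor(np.log2(n / support))) if n >= support else 0
        raise ScaleFeasibilityError(
            f"signal of length {n} supports at most octave {feasible} "
            f"with the {wavelet} filter (length {support}), octave {max_scale} requested",
            max_feasible=feasible,
        )
    coeffs: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    a = signal
    valid = np.ones(signal.shape, bool)
    for j in range(1, max_scale + 1):
        n_out = a.shape[-1] // 2
        d, dv = _analysis_step(a, valid, filt_hi, n_out)
        a, valid = _analysis_step(a, valid, filt_lo, n_out)
        coeffs.append(d * 2.0 ** (-j / 2.0))  # L1 normalization
        masks.append(dv)
    return LeaderPyramid(coeffs, masks, wavelet=wavelet, sampling_rate=sampling_rate)


def _children(prev: np.ndarray, prev_valid: np.ndarray, n_j: int):
    """Pairs (2k, 2k+1) of the previous octave aligned under node k of this octave."""
    need = 2 * n_j
    pad = need - prev.shape[-1]
    if pad > 0:
        prev = np.concatenate([prev, np.zeros(prev.shape[:-1] + (pad,))], axis=-1)
        prev_valid = np.concatenate(
            [prev_valid, np.zeros(prev_valid.shape[:-1] + (pad,), bool)], axis=-1
        )
    c0, c1 = prev[..., 0 : need : 2], prev[..., 1 : need : 2]
    v0, v1 = prev_valid[..., 0 : need : 2], prev_valid[..., 1 : need : 2]
    return np.maximum(c0, c1), v0 & v1


def compute_leaders(pyramid: LeaderPyramid) -> LeaderPyramid:
    """Fill the pyramid's wavelet leaders in place (and return it).

    ``L(j,k)`` is the supremum of ``|d(j',k')|`` over all dyadic intervals
    with ``j' <= j`` contained in the neighborhood ``lambda_{j,k-1} U
    lambda_{j,k} U lambda_{j,k+1}``.  Positions lacking a complete, fully
    valid neighborhood are flagged invalid.
    """
    if not pyramid.coefficients:
        raise StructuralError("pyramid has no coefficients")
    leaders: list[np.ndarray] = []
    lvalid: list[np.ndarray] = []
    sup = None  # running max over octaves <= j within lambda_{j,k}
    supv = None
    for j, (d, dv) in enumerate(zip(pyramid.coefficients, pyramid.coefficient_valid), start=1):
        n_j = d.shape[-1]
        if sup is None:
            sup, supv = np.abs(d), dv.copy()
        else:
            csup, cv = _children(sup, supv, n_j)
            sup = np.maximum(np.abs(d), csup)
            supv = dv & cv
        # three-neighborhood supremum; first/last positions lack a neighbor
        lead = np.full(sup.shape, np.nan)
        lv = np.zeros(supv.shape, bool)
        if n_j >= 3:
            lead[..., 1:-1] = np.maximum(
                np.maximum(sup[..., :-2], sup[..., 1:-1]), sup[..., 2:]
            )
            lv[..., 1:-1] = supv[..., :-2] & supv[..., 1:-1] & supv[..., 2:]
        leaders.append(lead)
        lvalid.append(lv)
    pyramid.leaders = leaders
    pyramid.leader_valid = lvalid
    return pyramid


@dataclass
class StructureFunctions:
    """S(j, q): average of the q-th power of valid leaders per octave."""

    q_grid: np.ndarray
    values: np.ndarray  # shape (..., n_q, n_scales)
    scales: np.ndarray  # octave indices
    #: False where a near-zero leader makes negative-q moments meaningless
    negative_q_valid: np.ndarray  # shape (...,)

    @property
    def log2_values(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.log2(self.values)


def _masked_leaders(pyramid: LeaderPyramid, j: int) -> tuple[np.ndarray, np.ndarray]:
    if pyramid.leaders is None:
        raise StructuralError("leaders not computed; call compute_leaders first")
    return pyramid.leaders[j - 1], pyramid.leader_valid[j - 1]


def _tiny_mask(lead: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """True where a valid leader is numerically zero relative to the window median."""
    with np.errstate(invalid="ignore"):
        med = np.nanmedian(np.where(valid, lead, np.nan), axis=-1, keepdims=True)
    return valid & ~(lead > TINY_LEADER_FACTOR * med)


def structure_functions(pyramid: LeaderPyramid, q_grid) -> StructureFunctions:
    """Structure functions over valid leaders for every octave of the pyramid.

    A window (batch element) containing a numerically zero valid leader is
    flagged invalid for negative orders rather than raising.
    """
    q = np.asarray(q_grid, dtype=float)
    scales = np.arange(1, pyramid.max_scale + 1)
    lead0, v0 = _masked_leaders(pyramid, 1)
    batch_shape = lead0.shape[:-1]
    values = np.empty(batch_shape + (q.size, scales.size))
    neg_ok = np.ones(batch_shape, bool)
    for idx, j in enumerate(scales):
        lead, valid = _masked_leaders(pyramid, j)
        neg_ok &= ~_tiny_mask(lead, valid).any(axis=-1)
        count = np.maximum(valid.sum(axis=-1), 1)
        safe = np.where(valid, lead, 1.0)
        with np.errstate(divide="ignore", over="ignore"):
            powed = safe[..., None, :] ** q[:, None]
        values[..., idx] = np.where(valid[..., None, :], powed, 0.0).sum(axis=-1) / count[
            ..., None
        ]
    return StructureFunctions(q_grid=q, values=values, scales=scales, negative_q_valid=neg_ok)


def _slope_weights(x: np.ndarray) -> np.ndarray:
    xc = x - x.mean()
    return xc / np.sum(xc**2)


def zeta_estimates(sf: StructureFunctions, j1: int, j2: int) -> np.ndarray:
    """Scaling exponents zeta(q): OLS slope of log2 S(j,q) on j over [j1, j2]."""
    if j2 <= j1:
        raise ParameterError("j2 must exceed j1")
    sel = (sf.scales >= j1) & (sf.scales <= j2)
    if sel.sum() < 2:
        raise ParameterError(f"octaves [{j1}, {j2}] not present in the structure functions")
    w = _slope_weights(sf.scales[sel].astype(float))
    return np.einsum("...qs,s->...q", sf.log2_values[..., sel], w)


def _per_scale_log_stats(
    pyramid: LeaderPyramid, scales: np.ndarray, min_leaders: int
) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
    """ln-leader arrays and validity masks per octave, plus overall window validity."""
    xs, vs = [], []
    lead0, _ = _masked_leaders(pyramid, int(scales[0]))
    ok = np.ones(lead0.shape[:-1], bool)
    for j in scales:
        lead, valid = _masked_leaders(pyramid, int(j))
        use = valid & ~_tiny_mask(lead, valid)
        with np.errstate(divide="ignore", invalid="ignore"):
            x = np.where(use, np.log(np.where(use, lead, 1.0)), np.nan)
        ok &= use.sum(axis=-1) >= min_leaders
        xs.append(x)
        vs.append(use)
    return xs, vs, ok


def _cumulants_from_stats(means: np.ndarray, variances: np.ndarray, scales: np.ndarray):
    """Regress per-scale mean/variance of ln-leaders on j ln 2 -> (c1, c2)."""
    w = _slope_weights(scales.astype(float)) / np.log(2.0)
    c1 = np.einsum("...s,s->...", means, w)
    c2 = np.einsum("...s,s->...", variances, w)
    return c1, c2


def log_cumulants(
    pyramid: LeaderPyramid,
    j1: int,
    j2: int,
    min_leaders: int = MIN_LEADERS_PER_SCALE,
) -> tuple[np.ndarray, np.ndarray]:
    """Plug-in log-cumulant estimates (c1, c2) over octaves [j1, j2].

    Per octave, ``C1(j)`` is the sample mean and ``C2(j)`` the unbiased
    sample variance of ``ln L(j, .)`` over valid leaders; ``c_p`` is the OLS
    slope of ``Cp(j)`` against ``j ln 2``.  Windows where any octave retains
    fewer than ``min_leaders`` valid leaders yield NaN.
    """
    if j2 <= j1:
        raise ParameterError("j2 must exceed j1")
    if j2 > pyramid.max_scale:
        raise ParameterError(f"octave {j2} not present (max {pyramid.max_scale})")
    scales = np.arange(j1, j2 + 1)
    xs, vs, ok = _per_scale_log_stats(pyramid, scales, min_leaders)
    means = np.stack(
        [np.where(v.any(-1), np.nansum(np.where(v, x, 0.0), -1) / np.maximum(v.sum(-1), 1), np.nan)
         for x, v in zip(xs, vs)],
        axis=-1,
    )
    variances = []
    for x, v in zip(xs, vs):
        cnt = v.sum(-1)
        m = np.nansum(np.where(v, x, 0.0), -1) / np.maximum(cnt, 1)
        ss = np.nansum(np.where(v, (x - m[..., None]) ** 2, 0.0), -1)
        variances.append(np.where(cnt > 1, ss / np.maximum(cnt - 1, 1), np.nan))
    variances = np.stack(variances, axis=-1)
    c1, c2 = _cumulants_from_stats(means, variances, scales)
    nan = np.where(ok, 1.0, np.nan)
    return c1 * nan, c2 * nan


@dataclass
class ScalingEstimate:
    """Bootstrap log-cumulant estimate for one window (or a batch of windows)."""

    c1: np.ndarray
    c2: np.ndarray
    bootstrap_c1: np.ndarray  # shape (..., R)
    bootstrap_c2: np.ndarray
    scale_range: tuple[int, int]
    R: int
    valid: np.ndarray
    zeta: np.ndarray | None = None
    q_grid: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "c1": np.asarray(self.c1).tolist(),
            "c2": np.asarray(self.c2).tolist(),
            "bootstrap_c1": np.asarray(self.bootstrap_c1).tolist(),
            "bootstrap_c2": np.asarray(self.bootstrap_c2).tolist(),
            "scale_range": list(self.scale_range),
            "R": self.R,
            "valid": np.asarray(self.valid).tolist(),
            "zeta": None if self.zeta is None else np.asarray(self.zeta).tolist(),
            "q_grid": None if self.q_grid is None else np.asarray(self.q_grid).tolist(),
        }


def bootstrap_cumulants(
    pyramid: LeaderPyramid,
    j1: int,
    j2: int,
    R: int = 100,
    seed=None,
    q_grid=None,
    min_leaders: int = MIN_LEADERS_PER_SCALE,
    identity_resample: bool = False,
) -> ScalingEstimate:
    """Bootstrap log-cumulants: resample leaders within each octave, average.

    At each octave the valid leaders are resampled with replacement,
    independently across octaves (and across windows of a batch); each of the
    ``R`` resamples yields a cumulant estimate as in :func:`log_cumulants`,
    and the reported ``c1, c2`` are the means over the ``R`` replicates.
    ``identity_resample=True`` is a test hook that replaces every resample
    with the original sample, making the result equal the plug-in estimate.
    """
    if R < 1:
        raise ParameterError("R must be >= 1")
    scales = np.arange(j1, j2 + 1)
    if j2 <= j1:
        raise ParameterError("j2 must exceed j1")
    if j2 > pyramid.max_scale:
        raise ParameterError(f"octave {j2} not present (max {pyramid.max_scale})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xs, vs, ok = _per_scale_log_stats(pyramid, scales, min_leaders)

    boot_means, boot_vars = [], []
    for x, v in zip(xs, vs):
        n_j = x.shape[-1]
        uniform = v.ndim >= 2 and bool((v == v[(0,) * (v.ndim - 1)]).all())
        if uniform or v.ndim == 1:
            # common case: every window of the batch has the same valid set
            first = v if v.ndim == 1 else v[(0,) * (v.ndim - 1)]
            cols = np.flatnonzero(first)
            c = max(cols.size, 1)
            xc = x[..., cols]
            if identity_resample:
                idx = np.broadcast_to(np.arange(c), x.shape[:-1] + (R, c))
            else:
                idx = rng.integers(0, c, size=x.shape[:-1] + (R, c), dtype=np.int32)
            draws = np.take_along_axis(xc[..., None, :], idx, axis=-1)
            m = draws.mean(axis=-1)
            var = ((draws - m[..., None]) ** 2).sum(-1) / max(c - 1, 1)
        else:
            order = np.argsort(~v, axis=-1, kind="stable")  # valid entries first
            xc = np.take_along_axis(np.where(v, x, 0.0), order, axis=-1)
            cnt = v.sum(axis=-1)  # shape (...,)
            cnt_safe = np.maximum(cnt, 1)
            if identity_resample:
                idx = np.broadcast_to(
                    np.arange(n_j), x.shape[:-1] + (R, n_j)
                ) % cnt_safe[..., None, None]
            else:
                u = rng.random(x.shape[:-1] + (R, n_j))
                idx = (u * cnt_safe[..., None, None]).astype(np.intp)
            draw_mask = np.arange(n_j) < cnt[..., None, None]
            draws = np.take_along_axis(xc[..., None, :], idx, axis=-1)
            m = np.where(draw_mask, draws, 0.0).sum(-1) / cnt_safe[..., None]
            ss = np.where(draw_mask, (draws - m[..., None]) ** 2, 0.0).sum(-1)
            var = ss / np.maximum(cnt_safe - 1, 1)[..., None]
        boot_means.append(m)
        boot_vars.append(var)
    bmeans = np.stack(boot_means, axis=-1)  # (..., R, n_scales)
    bvars = np.stack(boot_vars, axis=-1)
    bc1, bc2 = _cumulants_from_stats(bmeans, bvars, scales)  # (..., R)
    nan = np.where(ok, 1.0, np.nan)
    zeta = None
    q = None
    if q_grid is not None:
        q = np.asarray(q_grid, dtype=float)
        zeta = zeta_estimates(structure_functions(pyramid, q), j1, j2)
    return ScalingEstimate(
        c1=bc1.mean(axis=-1) * nan,
        c2=bc2.mean(axis=-1) * nan,
        bootstrap_c1=bc1,
        bootstrap_c2=bc2,
        scale_range=(j1, j2),
        R=R,
        valid=ok,
        zeta=zeta,
        q_grid=q,
    )
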