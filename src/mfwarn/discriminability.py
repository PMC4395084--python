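"""Preictal-vs-interictal statistical comparison on 5-min epoch averages.

Feature observations (cumulants or band powers) are averaged inside 5-min
epochs; the preictal and interictal epoch averages are compared per channel
with a two-tailed Wilcoxon rank-sum test (midrank ties, tie-corrected
normal approximation with continuity correction), Bonferroni-corrected over
channels.  Channels are ranked by |z|; significance tiers are reported at
corrected p < 0.01 and < 0.001, with the direction of the preictal-minus-
interictal mean difference.  The confounder table juxtaposes the cumulant
comparison with band-power comparisons on each cumulant's most
discriminating channel, to show whether a cumulant difference could be
explained by spectral power alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .exceptions import ParameterError
from .features import BandPowerSeries, CumulantSeries

__all__ = [
    "Epoch",
    "EpochAverages",
    "DiscriminabilityResult",
    "epoch_average",
    "ranksum_test",
    "bonferroni",
    "channel_discriminability",
    "confounder_table",
]

logger = logging.getLogger(__name__)

EPOCH_LENGTH_S = 300.0


@dataclass(frozen=True)
class Epoch:
    """A half-open [start, end) interval tagged 'preictal' or 'interictal'."""

    start: float
    end: float
    label: str

    def __post_init__(self):
        if self.end <= self.start:
            raise ParameterError(f"empty epoch [{self.start}, {self.end})")
        if self.label not in ("preictal", "interictal"):
            raise ParameterError(f"unknown epoch label {self.label!r}")


@dataclass
class EpochAverages:
    """Per-channel, per-class lists of epoch-mean feature values."""

    feature: str
    channel_labels: list[str]
    preictal: np.ndarray  # (n_channels, n_preictal_epochs)
    interictal: np.ndarray
    epochs: list[Epoch] = field(default_factory=list)


def epoch_average(series, epochs: list[Epoch], feature: str) -> EpochAverages:
    """Mean of valid 1-min windows fully inside each epoch, per channel.

    Epochs in which a channel has zero valid windows are dropped for that
    channel (recorded as NaN and skipped downstream) with a logged warning.
    """
    values = series.feature(feature)
    starts = series.window_starts
    length = series.window_length
    out = {"preictal": [], "interictal": []}
    kept: list[Epoch] = []
    for ep in epochs:
        inside = (starts >= ep.start) & (starts + length <= ep.end)
        v = np.where(series.valid[:, inside], values[:, inside], np.nan)
        if np.all(np.isnan(v)):
            logger.warning("epoch [%s, %s) has no valid windows; dropped", ep.start, ep.end)
            continue
        with np.errstate(invalid="ignore"):
            means = np.nanmean(v, axis=1)
        if np.isnan(means).any():
            logger.warning(
                "epoch [%s, %s): %d channel(s) with no valid windows",
                ep.start, ep.end, int(np.isnan(means).sum()),
            )
        out[ep.label].append(means)
        kept.append(ep)
    pre = np.array(out["preictal"]).T if out["preictal"] else np.empty((len(series.channel_labels), 0))
    inter = np.array(out["interictal"]).T if out["interictal"] else np.empty((len(series.channel_labels), 0))
    return EpochAverages(
        feature=feature,
        channel_labels=list(series.channel_labels),
        preictal=pre,
        interictal=inter,
        epochs=kept,
    )


def ranksum_test(group_a, group_b) -> tuple[float, float]:
    """Two-tailed Wilcoxon rank-sum test; returns (z, two_sided_p).

    Midranks for ties, normal approximation with tie-corrected variance and
    a 0.5 continuity correction.  z > 0 means ``group_a`` is stochastically
    larger than ``group_b``.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ParameterError("both groups need at least 2 observations")
    pooled = np.concatenate([a, b])
    ranks = spstats.rankdata(pooled)  # midranks
    w = ranks[:n1].sum()
    mu = n1 * (n1 + n2 + 1) / 2.0
    # tie correction on the variance
    _, counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    var = n1 * n2 / 12.0 * ((n + 1) - (counts**3 - counts).sum() / (n * (n - 1)))
    if var <= 0:
        return 0.0, 1.0
    diff = w - mu
    cc = 0.5 if diff != 0 else 0.0
    z = (diff - np.sign(diff) * cc) / np.sqrt(var)
    p = 2.0 * spstats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected p-value: min(1, p * m)."""
    if not 0.0 <= p <= 1.0:
        raise ParameterError("p must be in [0, 1]")
    if m < 1:
        raise ParameterError("m must be >= 1")
    return min(1.0, p * m)


@dataclass
class ChannelComparison:
    channel: str
    z: float
    p_raw: float
    p_corrected: float
    direction: str  # 'up' preictal mean > interictal mean, else 'down'
    tier: str  # '++', '+', 'n.s.'


@dataclass
class DiscriminabilityResult:
    feature: str
    channels: list[ChannelComparison]
    most_discriminating_channel: str | None

    def by_channel(self, label: str) -> ChannelComparison:
        return next(c for c in self.channels if c.channel == label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "channel": c.channel,
                    "z": c.z,
                    "p_raw": c.p_raw,
                    "p_corrected": c.p_corrected,
                    "direction": c.direction,
                    "tier": c.tier,
                }
                for c in self.channels
            ]
        )


def _tier(p_corr: float) -> str:
    if p_corr < 0.001:
        return "++"
    if p_corr < 0.01:
        return "+"
    return "n.s."


def channel_discriminability(averages: EpochAverages) -> DiscriminabilityResult:
    """Rank-sum comparison of preictal vs interictal epoch averages per channel."""
    n_ch = len(averages.channel_labels)
    comparisons = []
    for i, label in enumerate(averages.channel_labels):
        pre = averages.preictal[i]
        inter = averages.interictal[i]
        z, p = ranksum_test(pre, inter)
        p_corr = bonferroni(p, n_ch)
        direction = "up" if np.nanmean(pre) > np.nanmean(inter) else "down"
        comparisons.append(ChannelComparison(label, z, p, p_corr, direction, _tier(p_corr)))
    significant = [c for c in comparisons if c.tier != "n.s."]
    best = max(significant, key=lambda c: abs(c.z)).channel if significant else None
    return DiscriminabilityResult(averages.feature, comparisons, best)


def confounder_table(
    cumulant_results: dict[str, DiscriminabilityResult],
    band_results: dict[str, DiscriminabilityResult],
) -> pd.DataFrame:
    """Per-patient significance table: cumulants vs band powers.

    One row per cumulant ('c1', 'c2'): its tier and direction on its most
    discriminating channel, followed by the band-power tiers evaluated on
    that same channel.  Mirrors the structure of the published comparison
    table (tier symbols ++ / + / n.s., direction arrows).
    """
    rows = []
    for feat, res in cumulant_results.items():
        ch = res.most_discriminating_channel
        if ch is None:
            ch = max(res.channels, key=lambda c: abs(c.z)).channel
        comp = res.by_channel(ch)
        row = {
            "feature": feat,
            "channel": ch,
            "tier": comp.tier,
            "direction": {"up": "↑", "down": "↓"}[comp.direction],
        }
        for band, bres in band_results.items():
            row[band] = bres.by_channel(ch).tier
        rows.append(row)
    return pd.DataFrame(rows)
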