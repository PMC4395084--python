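"""Multichannel recording container with seizure annotations and gaps.

A :class:`Recording` holds uniformly sampled multichannel data (microvolts)
together with the metadata the prediction pipeline needs: sampling rate,
channel labels (typically bipolar pairs), half-open gap intervals during
which no valid data exist, and seizure onset times.  All times are seconds
from the start of the recording; intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError

__all__ = ["Recording"]


@dataclass
class Recording:
    samples: np.ndarray  # shape (n_channels, n_samples), microvolts
    sampling_rate: float  # Hz
    channel_labels: list[str]
    gaps: list[tuple[float, float]] = field(default_factory=list)
    seizure_onsets: list[float] = field(default_factory=list)
    split_tag: str = "training"  # "training" | "testing"

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be positive")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ParameterError(
                f"{len(self.channel_labels)} labels for {self.samples.shape[0]} channels"
            )
        dur = self.duration
        for t in self.seizure_onsets:
            if not (0 <= t <= dur):
                raise ParameterError(f"seizure onset {t} s outside recording of {dur} s")
        gaps = sorted((float(a), float(b)) for a, b in self.gaps)
        for (a, b) in gaps:
            if b <= a:
                raise ParameterError(f"empty or inverted gap [{a}, {b})")
        for (_, b0), (a1, _) in zip(gaps, gaps[1:]):
            if a1 < b0:
                raise ParameterError("gaps must be pairwise disjoint")
        self.gaps = gaps
        self.seizure_onsets = sorted(float(t) for t in self.seizure_onsets)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording span in seconds."""
        return self.n_samples / self.sampling_rate

    def in_gap(self, start: float, end: float) -> bool:
        """True if the half-open window [start, end) intersects any gap."""
        return any(a < end and start < b for a, b in self.gaps)
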