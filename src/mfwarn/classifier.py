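"""Patient-specific per-channel discriminant training and window classification.

Training: every valid 1-min window fully inside a labeled epoch becomes one
feature observation; each channel gets its own linear discriminant (pooled
covariance, equal priors), scored by stratified 10-fold cross-validation
with balanced accuracy — (sensitivity + specificity) / 2 — and the three
highest-scoring channels are retained.  Testing: the per-channel
discriminants label every valid window 'preictal' or 'interictal' and the
channel decisions are combined by majority vote (ties resolve to
'interictal', biasing against false warnings).

Feature sets: FS1 = c1, FS2 = c2, FS3 = c1 + c2; FS4–FS6 additionally take
externally supplied feature columns (``CumulantSeries.extras``), standing in
for the state-similarity measures of the companion method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from ._seeding import as_int_seed, spawn_generators
from .discriminability import Epoch
from .exceptions import ConfigurationError, ParameterError, TrainingError
from .features import CumulantSeries

__all__ = [
    "FEATURE_SETS",
    "ChannelModel",
    "TrainedDetector",
    "label_training_windows",
    "crossvalidate_channel",
    "select_top_channels",
    "train_detector",
    "classify_windows",
    "majority_vote",
]

logger = logging.getLogger(__name__)

PREICTAL, INTERICTAL, INVALID = 1, 0, -1

#: feature-set id -> base cumulant features; True marks sets that require extras
FEATURE_SETS: dict[str, tuple[list[str], bool]] = {
    "FS1": (["c1"], False),
    "FS2": (["c2"], False),
    "FS3": (["c1", "c2"], False),
    "FS4": (["c1"], True),
    "FS5": (["c2"], True),
    "FS6": (["c1", "c2"], True),
}


def _feature_columns(series: CumulantSeries, feature_set: str) -> list[str]:
    try:
        base, wants_extras = FEATURE_SETS[feature_set]
    except KeyError:
        raise ParameterError(f"unknown feature set {feature_set!r}") from None
    cols = list(base)
    if wants_extras:
        if not series.extras:
            raise ConfigurationError(
                f"feature set {feature_set} requires externally supplied extra feature columns"
            )
        cols += list(series.extras)
    return cols


def _fit_lda(X: np.ndarray, y: np.ndarray) -> LinearDiscriminantAnalysis:
    lda = LinearDiscriminantAnalysis(
        solver="lsqr", shrinkage=1e-6, priors=np.array([0.5, 0.5])
    )
    lda.fit(X, y)
    return lda


@dataclass
class ChannelModel:
    """A per-channel linear discriminant with its cross-validation score."""

    channel: str
    feature_set: str
    feature_names: list[str]
    weights: np.ndarray
    threshold: float
    score: float

    def decide(self, X: np.ndarray) -> np.ndarray:
        """1 = preictal, 0 = interictal for each row of X (NaN rows -> -1)."""
        out = np.full(X.shape[0], INVALID, dtype=int)
        ok = ~np.isnan(X).any(axis=1)
        out[ok] = (X[ok] @ self.weights + self.threshold > 0).astype(int)
        return out

    def to_dict(self) -> dict:
        return {
            "channel": self.channel,
            "feature_set": self.feature_set,
            "feature_names": self.feature_names,
            "weights": self.weights.tolist(),
            "threshold": self.threshold,
            "score": self.score,
        }


@dataclass
class TrainedDetector:
    """Top channels, their discriminants, and the decision parameters."""

    feature_set: str
    channels: list[ChannelModel]  # sorted by descending score
    consecutive_windows: int = 5
    windowing: dict = field(default_factory=dict)
    training_fingerprint: str = ""

    @property
    def channel_labels(self) -> list[str]:
        return [m.channel for m in self.channels]

    def to_dict(self) -> dict:
        return {
            "feature_set": self.feature_set,
            "channels": [m.to_dict() for m in self.channels],
            "consecutive_windows": self.consecutive_windows,
            "windowing": self.windowing,
            "training_fingerprint": self.training_fingerprint,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedDetector":
        chans = [
            ChannelModel(
                channel=m["channel"],
                feature_set=m["feature_set"],
                feature_names=list(m["feature_names"]),
                weights=np.asarray(m["weights"], float),
                threshold=float(m["threshold"]),
                score=float(m["score"]),
            )
            for m in d["channels"]
        ]
        return cls(
            feature_set=d["feature_set"],
            channels=chans,
            consecutive_windows=int(d.get("consecutive_windows", 5)),
            windowing=dict(d.get("windowing", {})),
            training_fingerprint=d.get("training_fingerprint", ""),
        )


def label_training_windows(
    series: CumulantSeries, epochs: list[Epoch], feature_set: str = "FS3"
) -> tuple[np.ndarray, np.ndarray]:
    """Feature observations and labels from valid windows fully inside epochs.

    Returns ``X`` of shape (n_channels, n_observations, n_features) and a
    label vector ``y`` (1 preictal, 0 interictal).  Windows straddling an
    epoch boundary are excluded.  Raises if either class ends up empty.
    """
    cols = _feature_columns(series, feature_set)
    starts = series.window_starts
    length = series.window_length
    X_parts, y_parts = [], []
    for ep in epochs:
        inside = np.flatnonzero((starts >= ep.start) & (starts + length <= ep.end))
        if inside.size == 0:
            continue
        feats = np.stack([series.feature(c)[:, inside] for c in cols], axis=-1)
        X_parts.append(feats)
        y_parts.append(np.full(inside.size, PREICTAL if ep.label == "preictal" else INTERICTAL))
    if not X_parts:
        raise TrainingError("no windows fall inside the training epochs")
    X = np.concatenate(X_parts, axis=1)
    y = np.concatenate(y_parts)
    for cls, name in ((PREICTAL, "preictal"), (INTERICTAL, "interictal")):
        if not np.any(y == cls):
            raise TrainingError(f"no valid {name} training observations")
    return X, y


def _balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    sens_mask = y_true == PREICTAL
    spec_mask = ~sens_mask
    sens = (y_pred[sens_mask] == PREICTAL).mean() if sens_mask.any() else np.nan
    spec = (y_pred[spec_mask] == INTERICTAL).mean() if spec_mask.any() else np.nan
    return float(np.nanmean([sens, spec]))


def crossvalidate_channel(
    observations: np.ndarray,
    labels: np.ndarray,
    n_folds: int = 10,
    seed=None,
    scheme: str = "stratified_kfold",
    shuffle: bool = False,
) -> float:
    """Cross-validated balanced accuracy of a per-channel linear discriminant.

    Stratified k-fold (each fold held out once) by default; ``scheme='loo'``
    gives literal leave-one-out, scored on the pooled held-out predictions.
    Fold assignment is deterministic (contiguous stratified blocks, no
    shuffling), which keeps channel scoring reproducible and exactly
    permutation-equivariant across channels; pass ``shuffle=True`` with a
    seed for randomized folds.  Folds are refolded with a smaller k (logged)
    if a class cannot populate every fold.
    """
    ok = ~np.isnan(observations).any(axis=1)
    X, y = observations[ok], labels[ok]
    if np.unique(y).size < 2:
        raise TrainingError("both classes must be present for cross-validation")
    if scheme == "loo":
        preds = np.empty_like(y)
        for tr, te in LeaveOneOut().split(X):
            preds[te] = _fit_lda(X[tr], y[tr]).predict(X[te])
        return _balanced_accuracy(y, preds)
    min_class = int(np.bincount(y).min())
    k = min(n_folds, min_class)
    if k < n_folds:
        logger.warning("refolding with %d folds (smallest class has %d members)", k, min_class)
    if k < 2:
        raise TrainingError("smallest class too small for cross-validation")
    if X.shape[0] < n_folds:
        raise TrainingError(f"need at least {n_folds} observations, got {X.shape[0]}")
    rs = as_int_seed(seed) if shuffle else None
    skf = StratifiedKFold(n_splits=k, shuffle=shuffle, random_state=rs)
    scores = [
        _balanced_accuracy(y[te], _fit_lda(X[tr], y[tr]).predict(X[te]))
        for tr, te in skf.split(X, y)
    ]
    return float(np.mean(scores))


def select_top_channels(scores: dict[str, float], k: int = 3) -> list[str]:
    """The k channels with the highest scores; ties break lexicographically."""
    if not scores:
        raise ParameterError("at least one channel must be scored")
    ranked = sorted(scores, key=lambda ch: (-scores[ch], ch))
    if len(ranked) < k:
        logger.warning("only %d channels available for top-%d selection", len(ranked), k)
    return ranked[:k]


def train_detector(
    series: CumulantSeries,
    epochs: list[Epoch],
    feature_set: str = "FS3",
    k: int = 3,
    n_folds: int = 10,
    seed=None,
    scheme: str = "stratified_kfold",
) -> TrainedDetector:
    """Steps 1-3 of the training procedure: score channels, keep the top k."""
    X, y = label_training_windows(series, epochs, feature_set)
    cols = _feature_columns(series, feature_set)
    child = spawn_generators(seed, series.n_channels)
    scores: dict[str, float] = {}
    models: dict[str, ChannelModel] = {}
    for i, ch in enumerate(series.channel_labels):
        score = crossvalidate_channel(
            X[i], y, n_folds=n_folds, seed=child[i], scheme=scheme
        )
        ok = ~np.isnan(X[i]).any(axis=1)
        lda = _fit_lda(X[i][ok], y[ok])
        models[ch] = ChannelModel(
            channel=ch,
            feature_set=feature_set,
            feature_names=cols,
            weights=lda.coef_.ravel().copy(),
            threshold=float(lda.intercept_[0]),
            score=score,
        )
        scores[ch] = score
    selected = select_top_channels(scores, k=k)
    return TrainedDetector(
        feature_set=feature_set,
        channels=[models[ch] for ch in selected],
        windowing={
            "window_length_s": series.window_length,
            "step_s": series.step,
            **series.provenance,
        },
        training_fingerprint=f"n_obs={y.size},n_pre={int((y == PREICTAL).sum())}",
    )


def classify_windows(detector: TrainedDetector, series: CumulantSeries) -> np.ndarray:
    """Per-channel, per-window labels (1 preictal / 0 interictal / -1 invalid)."""
    missing = [ch for ch in detector.channel_labels if ch not in series.channel_labels]
    if missing:
        raise ConfigurationError(f"test series lacks detector channels: {missing}")
    cols = _feature_columns(series, detector.feature_set)
    labels = np.full((len(detector.channels), series.window_starts.size), INVALID, int)
    for row, model in enumerate(detector.channels):
        i = series.channel_labels.index(model.channel)
        X = np.stack([series.feature(c)[i] for c in cols], axis=-1)
        X = np.where(series.valid[i][:, None], X, np.nan)
        labels[row] = model.decide(X)
    return labels


def majority_vote(channel_labels: np.ndarray) -> np.ndarray:
    """Aggregate per-channel window labels by majority; ties -> interictal.

    A window with zero valid channel decisions stays invalid (-1).
    """
    labels = np.atleast_2d(np.asarray(channel_labels))
    valid = labels != INVALID
    n_valid = valid.sum(axis=0)
    n_pre = ((labels == PREICTAL) & valid).sum(axis=0)
    out = np.where(n_pre * 2 > n_valid, PREICTAL, INTERICTAL)
    out[n_valid == 0] = INVALID
    return out
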