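"""Per-channel discriminant training, channel selection, majority voting."""

import numpy as np
import pytest

from mfwarn.classifier import (
    INTERICTAL,
    INVALID,
    PREICTAL,
    classify_windows,
    crossvalidate_channel,
    label_training_windows,
    majority_vote,
    select_top_channels,
    train_detector,
)
from mfwarn.discriminability import Epoch
from mfwarn.exceptions import ConfigurationError, ParameterError, TrainingError

from conftest import make_series


def gaussian_clouds(rng, n=100, sep=6.0, d=2):
    X = np.vstack([rng.normal(0, 1, (n // 2, d)), rng.normal(sep, 1, (n // 2, d))])
    y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
    return X, y


def shifted_series(rng, shifts, n_windows=200, preictal_span=(0.0, 600.0)):
    """Series where affected channels' c1 is shifted inside the preictal span."""
    n_ch = len(shifts)
    c1 = rng.normal(0.0, 0.05, (n_ch, n_windows))
    series = make_series(n_channels=n_ch, n_windows=n_windows, c1=c1)
    sel = (series.window_starts >= preictal_span[0]) & (
        series.window_starts + 60 <= preictal_span[1]
    )
    series.c1[:, sel] += np.asarray(shifts, float)[:, None]
    epochs = [
        Epoch(preictal_span[0], preictal_span[1], "preictal"),
        Epoch(preictal_span[1] + 60, series.window_starts[-1] + 75, "interictal"),
    ]
    return series, epochs


class TestLabeling:
    def test_ten_minute_epoch_yields_37_observations(self):
        series = make_series(n_channels=1, n_windows=80)
        X, y = label_training_windows(
            series, [Epoch(0.0, 600.0, "preictal"), Epoch(660.0, 1000.0, "interictal")]
        )
        assert (y == PREICTAL).sum() == 37  # floor((600-60)/15)+1

    def test_straddling_window_excluded(self):
        series = make_series(n_channels=1, n_windows=40)
        X, y = label_training_windows(
            series,
            [Epoch(0.0, 70.0, "preictal"), Epoch(120.0, 300.0, "interictal")],
        )
        # only the window starting at 0 fits inside [0, 70)
        assert (y == PREICTAL).sum() == 1

    def test_missing_class_raises(self):
        series = make_series(n_channels=1, n_windows=40)
        with pytest.raises(TrainingError):
            label_training_windows(series, [Epoch(0.0, 300.0, "preictal")])


class TestCrossValidation:
    def test_separable_clouds_score_high(self, rng):
        X, y = gaussian_clouds(rng, n=100)
        assert crossvalidate_channel(X, y, seed=0) >= 0.95

    def test_deterministic_given_seed(self, rng):
        X, y = gaussian_clouds(rng, n=60, sep=1.0)
        assert crossvalidate_channel(X, y, seed=3) == crossvalidate_channel(X, y, seed=3)

    def test_loo_mode(self, rng):
        X, y = gaussian_clouds(rng, n=40)
        assert crossvalidate_channel(X, y, scheme="loo") >= 0.95

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(30, 2))
        with pytest.raises(TrainingError):
            crossvalidate_channel(X, np.zeros(30, int))

    def test_permuted_labels_score_near_half(self, rng):
        # informative features, shuffled labels: balanced accuracy ~ 0.5
        scores = []
        for i in range(150):
            X, y = gaussian_clouds(rng, n=40, sep=4.0)
            rng.shuffle(y)
            scores.append(crossvalidate_channel(X, y, seed=i))
        assert np.mean(scores) == pytest.approx(0.5, abs=0.05)


class TestSelection:
    def test_top_three_by_score(self):
        scores = {"A": 0.9, "B": 0.8, "C": 0.7, "D": 0.6}
        assert select_top_channels(scores) == ["A", "B", "C"]

    def test_fewer_channels_than_k(self):
        assert select_top_channels({"A": 0.6, "B": 0.9}, k=3) == ["B", "A"]

    def test_tie_breaks_lexicographically(self):
        assert select_top_channels({"B": 0.8, "A": 0.8, "C": 0.1}, k=2) == ["A", "B"]

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            select_top_channels({})


class TestDetector:
    def test_selects_informative_channels(self, rng):
        series, epochs = shifted_series(rng, [0.5, 0.5, 0.0, 0.5])
        det = train_detector(series, epochs, feature_set="FS1", seed=0)
        assert set(det.channel_labels) == {"CH0", "CH1", "CH3"}
        assert [m.score for m in det.channels] == sorted(
            (m.score for m in det.channels), reverse=True
        )

    def test_channel_permutation_equivariance(self, rng):
        # distinct score levels: with tied scores the lexicographic
        # tie-break is deliberately label-dependent
        series, epochs = shifted_series(rng, [0.5, 0.0, 0.08])
        det = train_detector(series, epochs, feature_set="FS1", seed=0)
        scores = sorted(m.score for m in det.channels)
        assert len(set(scores)) == len(scores)
        # relabel channels: permutation of labels permutes the selection
        perm = [2, 0, 1]
        series2 = make_series(
            n_channels=3,
            n_windows=series.window_starts.size,
            c1=series.c1[perm],
            labels=[f"CH{i}" for i in range(3)],
        )
        det2 = train_detector(series2, epochs, feature_set="FS1", seed=0)
        # new channel i carries the data of original channel perm[i]
        relabel = {f"CH{i}": f"CH{j}" for i, j in enumerate(perm)}
        assert [relabel[ch] for ch in det2.channel_labels] == det.channel_labels

    def test_roundtrip_through_dict(self, rng):
        from mfwarn.classifier import TrainedDetector

        series, epochs = shifted_series(rng, [0.4, 0.0, 0.2])
        det = train_detector(series, epochs, feature_set="FS3", seed=1)
        clone = TrainedDetector.from_dict(det.to_dict())
        labels = classify_windows(det, series)
        np.testing.assert_array_equal(labels, classify_windows(clone, series))

    def test_feature_set_requiring_extras_raises_without_them(self, rng):
        series, epochs = shifted_series(rng, [0.4, 0.0])
        with pytest.raises(ConfigurationError):
            train_detector(series, epochs, feature_set="FS4", seed=0)

    def test_extras_used_when_supplied(self, rng):
        series, epochs = shifted_series(rng, [0.4, 0.0])
        series.extras["similarity"] = rng.normal(size=series.c1.shape)
        det = train_detector(series, epochs, feature_set="FS4", seed=0)
        assert det.channels[0].feature_names == ["c1", "similarity"]


class TestClassification:
    def test_preictal_centroid_labeled_preictal(self, rng):
        series, epochs = shifted_series(rng, [0.5, 0.5, 0.5])
        det = train_detector(series, epochs, feature_set="FS1", seed=0)
        labels = classify_windows(det, series)
        pre_sel = (series.window_starts >= 0) & (series.window_starts + 60 <= 600)
        assert (labels[:, pre_sel] == PREICTAL).mean() > 0.9
        inter_sel = series.window_starts >= 700
        assert (labels[:, inter_sel] == INTERICTAL).mean() > 0.9

    def test_invalid_windows_stay_invalid(self, rng):
        series, epochs = shifted_series(rng, [0.5, 0.5, 0.5])
        series.valid[:, 5] = False
        det = train_detector(series, epochs, feature_set="FS1", seed=0)
        labels = classify_windows(det, series)
        assert np.all(labels[:, 5] == INVALID)

    def test_missing_channel_raises(self, rng):
        series, epochs = shifted_series(rng, [0.5, 0.5, 0.5])
        det = train_detector(series, epochs, feature_set="FS1", seed=0)
        other = make_series(n_channels=1, n_windows=40, labels=["OTHER"])
        with pytest.raises(ConfigurationError):
            classify_windows(det, other)


class TestMajorityVote:
    @pytest.mark.parametrize(
        "votes,expected",
        [
            ([PREICTAL, PREICTAL, INTERICTAL], PREICTAL),
            ([PREICTAL, INTERICTAL, INTERICTAL], INTERICTAL),
            ([PREICTAL, INTERICTAL, INVALID], INTERICTAL),  # tie -> interictal
            ([PREICTAL, PREICTAL, INVALID], PREICTAL),
            ([INVALID, INVALID, INVALID], INVALID),
        ],
    )
    def test_vote_rules(self, votes, expected):
        out = majority_vote(np.array(votes)[:, None])
        assert out[0] == expected
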