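"""End-to-end orchestration: simulate -> features -> train -> classify -> warn -> evaluate.

The library entry point is :func:`run_patient`, which takes a training and a
testing Recording plus labeled training epochs and returns the trained
detector together with one performance report per persistence-tau value.
:func:`run_pipeline` is the disk-artifact version used by the CLI: it
simulates (or reads) the recordings, writes every intermediate artifact and
a manifest, and emits the final JSON report with Benjamini-Hochberg
q-values across the tau grid and the critical-rate row.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .classifier import TrainedDetector, classify_windows, majority_vote, train_detector
from .discriminability import Epoch
from .evaluation import (
    PerformanceReport,
    bh_qvalues,
    evaluate_timeline,
    performance_at_critical_fpr,
)
from .exceptions import ConfigurationError, LeakageError
from .features import CumulantSeries, cumulant_series
from .io import (
    RunConfig,
    features_to_frame,
    read_epochs_csv,
    read_recording,
    save_json,
    write_epochs_csv,
    write_recording,
)
from .recording import Recording
from .synthetic import simulate_recording
from .warning_protocol import build_warning_timeline, detect_preictal_changes

__all__ = [
    "PatientResult",
    "default_synth_spec",
    "quick_study_config",
    "simulate_patient",
    "run_patient",
    "run_pipeline",
]


DEFAULT_SYNTH = {
    "n_channels": 3,
    "hurst": 0.6,
    "intermittency": 0.02,
    "c1_shift": 0.15,
    "affected_channels": [0, 1],
    "preictal_duration_s": 300.0,
    "train": {
        "duration_s": 3600.0,
        "seizure_times_s": [600.0, 1200.0],
        "interictal_epochs_s": [[1800.0, 2100.0], [2400.0, 2700.0], [3000.0, 3300.0]],
        "gaps_s": [],
    },
    "test": {
        "duration_s": 4800.0,
        "seizure_times_s": [1080.0, 2160.0, 3240.0, 4320.0],
        "gaps_s": [],
    },
}


def default_synth_spec() -> dict:
    return json.loads(json.dumps(DEFAULT_SYNTH))


def quick_study_config(
    c1_shift: float = 0.15,
    seed: int = 0,
    long_test: bool = True,
    R: int = 10,
    tau_grid_min: tuple[float, ...] = (3.0, 5.0, 8.0, 10.0),
) -> RunConfig:
    """A reduced-size synthetic study that runs in seconds per patient.

    Same pipeline, smaller problem: 500 Hz sampling with octaves 2-6 (the
    simulated process is scale-free, so this is statistically equivalent to
    2 kHz with octaves 3-7 at a quarter of the data volume), ``R`` bootstrap
    resamples, a 30-min training recording (two preictal and two interictal
    5-min epochs) and a monofractal background.  ``long_test=True`` gives a
    125-min test span with four seizures 30 min apart (low warning occupancy,
    so above-chance prediction is resolvable); ``False`` gives a 30-min test
    span with three seizures for cheap null-control runs.
    """
    if long_test:
        test = {
            "duration_s": 7500.0,
            "seizure_times_s": [1500.0, 3300.0, 5100.0, 6900.0],
            "gaps_s": [],
        }
    else:
        test = {
            "duration_s": 1800.0,
            "seizure_times_s": [600.0, 1080.0, 1560.0],
            "gaps_s": [],
        }
    return RunConfig(
        sampling_rate=500.0,
        scales=(2, 6),
        R=R,
        seed=seed,
        feature_set="FS3",
        tau_grid_min=list(tau_grid_min),
        synth={
            "n_channels": 3,
            "hurst": 0.6,
            "intermittency": 0.0,
            "c1_shift": c1_shift,
            "affected_channels": [0, 1],
            "preictal_duration_s": 300.0,
            "train": {
                "duration_s": 1800.0,
                "seizure_times_s": [420.0, 840.0],
                "interictal_epochs_s": [[960.0, 1260.0], [1320.0, 1620.0]],
                "gaps_s": [],
            },
            "test": test,
        },
    )


def simulate_patient(
    config: RunConfig, seed=None
) -> tuple[Recording, Recording, list[Epoch]]:
    """Simulate one synthetic patient (training + testing recordings, epochs)."""
    spec = {**default_synth_spec(), **(config.synth or {})}
    seed_seq = np.random.SeedSequence(config.seed if seed is None else seed)
    s_train, s_test = seed_seq.spawn(2)
    common = dict(
        n_channels=int(spec["n_channels"]),
        sampling_rate=config.sampling_rate,
        preictal_duration=float(spec["preictal_duration_s"]),
        c1_shift=float(spec["c1_shift"]),
        affected_channels=list(spec["affected_channels"]),
        hurst=float(spec["hurst"]),
        intermittency=float(spec["intermittency"]),
        c1_shift_mode=str(spec.get("c1_shift_mode", "hurst")),
    )
    tr = spec["train"]
    train_rec = simulate_recording(
        duration=float(tr["duration_s"]),
        seizure_times=list(tr["seizure_times_s"]),
        gap_spec=tr.get("gaps_s", []),
        seed=s_train,
        split_tag="training",
        **common,
    )
    te = spec["test"]
    test_rec = simulate_recording(
        duration=float(te["duration_s"]),
        seizure_times=list(te["seizure_times_s"]),
        gap_spec=te.get("gaps_s", []),
        seed=s_test,
        split_tag="testing",
        **common,
    )
    pre = float(spec["preictal_duration_s"])
    epochs = [Epoch(t - pre, t, "preictal") for t in tr["seizure_times_s"]]
    epochs += [Epoch(a, b, "interictal") for a, b in tr["interictal_epochs_s"]]
    return train_rec, test_rec, epochs


@dataclass
class PatientResult:
    detector: TrainedDetector
    votes: np.ndarray  # majority-vote labels on the test grid
    window_starts: np.ndarray
    detections: np.ndarray
    reports: list[PerformanceReport]  # one per persistence-tau
    train_series: CumulantSeries | None = None
    test_series: CumulantSeries | None = None

    def attach_qvalues(self) -> None:
        """BH q-values across this patient's tau grid."""
        qs = bh_qvalues([r.p_chance for r in self.reports])
        for r, q in zip(self.reports, qs):
            r.q_value = float(q)


def run_patient(
    train_rec: Recording,
    test_rec: Recording,
    train_epochs: list[Epoch],
    config: RunConfig,
    keep_series: bool = False,
) -> PatientResult:
    """Train on one recording, test on another, evaluate over the tau grid."""
    if train_rec is test_rec:
        raise LeakageError("training and testing recordings must be disjoint")
    seed_seq = np.random.SeedSequence(config.seed)
    s_ftr, s_fte, s_cv = seed_seq.spawn(3)
    kw = dict(
        scales=config.scales,
        q_grid=config.q_grid,
        R=config.R,
        sub_window=config.sub_window_s,
        window_length=config.window_s,
        step=config.step_s,
    )
    train_series = cumulant_series(train_rec, seed=s_ftr, **kw)
    test_series = cumulant_series(test_rec, seed=s_fte, **kw)
    detector = train_detector(
        train_series, train_epochs, feature_set=config.feature_set, seed=s_cv
    )
    detector.consecutive_windows = config.consecutive_windows
    labels = classify_windows(detector, test_series)
    votes = majority_vote(labels)
    detections = detect_preictal_changes(
        votes,
        test_series.window_starts,
        k=config.consecutive_windows,
        window_length=config.window_s,
    )
    reports = []
    for tau in config.tau_grid_min:
        timeline = build_warning_timeline(
            detections, tau, test_rec.gaps, (0.0, test_rec.duration)
        )
        reports.append(evaluate_timeline(timeline, test_rec.seizure_onsets))
    result = PatientResult(
        detector=detector,
        votes=votes,
        window_starts=test_series.window_starts,
        detections=detections,
        reports=reports,
        train_series=train_series if keep_series else None,
        test_series=test_series if keep_series else None,
    )
    result.attach_qvalues()
    return result


def _manifest(config: RunConfig) -> dict:
    import numpy
    import scipy

    cfg = config.to_dict()
    return {
        "package": "mfwarn",
        "version": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "seed": config.seed,
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
    }


def run_pipeline(
    config: RunConfig,
    outdir,
    train_edf=None,
    test_edf=None,
    train_epochs_csv=None,
) -> dict:
    """Full disk pipeline; returns the report dict it also writes to disk.

    With no EDF paths, a synthetic patient is simulated from
    ``config.synth``.  When paths are given, training and testing must be
    distinct files (same-file use would leak training data into testing).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        if train_edf is None and test_edf is None:
            train_rec, test_rec, epochs = simulate_patient(config)
            write_recording(outdir / "train", train_rec, stem="training")
            write_recording(outdir / "test", test_rec, stem="testing")
            write_epochs_csv(outdir / "train" / "epochs.csv", epochs)
        else:
            if train_edf is None or test_edf is None or train_epochs_csv is None:
                raise ConfigurationError(
                    "provide train_edf, test_edf and train_epochs_csv together"
                )
            if Path(train_edf).resolve() == Path(test_edf).resolve():
                raise LeakageError("training and testing EDF must be distinct files")
            train_rec = read_recording(train_edf, split_tag="training")
            test_rec = read_recording(test_edf, split_tag="testing")
            epochs = read_epochs_csv(train_epochs_csv)
            for ep in epochs:
                if ep.end > train_rec.duration:
                    raise ConfigurationError(
                        f"training epoch [{ep.start}, {ep.end}) exceeds the recording"
                    )
        stage = "features/train/classify/predict/evaluate"
        result = run_patient(train_rec, test_rec, epochs, config, keep_series=True)
    except Exception:
        save_json(outdir / "FAILED.json", {"stage": stage})
        raise
    features_to_frame(result.train_series).to_csv(outdir / "train_features.csv", index=False)
    features_to_frame(result.test_series).to_csv(outdir / "test_features.csv", index=False)
    save_json(outdir / "detector.json", result.detector.to_dict())
    np.savetxt(
        outdir / "votes.csv",
        np.column_stack([result.window_starts, result.votes]),
        delimiter=",",
        header="window_start_s,label",
        comments="",
        fmt="%.2f,%d",
    )
    report = {
        "per_tau": [r.to_dict() for r in result.reports],
        "critical_rate_row": performance_at_critical_fpr(
            result.reports, config.critical_fpr_per_h
        ),
        "n_detections": int(result.detections.size),
    }
    save_json(outdir / "report.json", report)
    save_json(outdir / "manifest.json", _manifest(config))
    return report
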