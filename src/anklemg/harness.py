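"""Experiment orchestration: container I/O, the intraload/interload matrix,
the two-step evaluation, and metrics.

The central object is a :class:`WindowDataset`: every 210 ms analysis
window of every trial with its feature tensor, per-channel RMS vector
(from the filtered, un-normalized signal, so it still carries load
information), raw samples, and labels. The one-step experiment trains a
movement model per load level and tests it under all three, yielding the
3x3 train-load x test-load accuracy matrix whose diagonal is "intraload"
and off-diagonal "interload" performance. The two-step experiment adds
the RMS-based load classifier and routes each test window to the
movement model of its predicted load.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold

from .features import FeatureSpec, extract_tensor
from .load_stage import LoadClassifier
from .movement_stage import CnnLstmClassifier, ModelSpec, TwoStepClassifier
from .preprocessing import (
    EmgRecording,
    WindowingSpec,
    bandpass_filter,
    normalize,
    notch_filter,
    segment_large,
    trim_trial,
)
from .synthetic_data import LOADS, MOVEMENTS, ProtocolSpec, Trial

__all__ = [
    "WindowDataset",
    "EvalReport",
    "OneStepResult",
    "save_trials",
    "load_trials",
    "preprocess_trial",
    "build_window_dataset",
    "split_dataset",
    "evaluate",
    "crossval_scores",
    "run_one_step_experiment",
    "run_two_step_experiment",
    "run_full_comparison",
    "default_config",
]


# --------------------------------------------------------------------------
# dataset container I/O
# --------------------------------------------------------------------------

def save_trials(directory: str | Path, trials: list[Trial]) -> None:
    """Write trials as one array file each plus a JSON manifest."""
    directory = Path(directory)
    (directory / "trials").mkdir(parents=True, exist_ok=True)
    manifest = {"units": "uV", "trials": []}
    for t in trials:
        fname = f"trials/trial_{t.trial_id:05d}.npy"
        np.save(directory / fname, t.recording.data)
        manifest["trials"].append(
            {
                "file": fname,
                "movement": t.movement,
                "load": t.load,
                "subject": t.subject,
                "repetition": t.repetition,
                "trial_id": t.trial_id,
                "fs": t.recording.fs,
                "channel_names": list(t.recording.channel_names),
                "filtered": t.recording.filtered,
                "normalized": t.recording.normalized,
                "protocol": {
                    "rest_s": t.protocol.rest_s,
                    "motion_s": t.protocol.motion_s,
                    "hold_s": t.protocol.hold_s,
                    "trim_ms": t.protocol.trim_ms,
                    "repetitions": t.protocol.repetitions,
                    "fs": t.protocol.fs,
                },
            }
        )
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_trials(directory: str | Path) -> list[Trial]:
    """Read a container written by :func:`save_trials`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    files = list((directory / "trials").glob("*.npy"))
    if len(files) != len(manifest["trials"]):
        raise ValueError(
            f"manifest lists {len(manifest['trials'])} trials but "
            f"{len(files)} array files are present"
        )
    trials = []
    for entry in manifest["trials"]:
        if entry["movement"] not in MOVEMENTS:
            raise ValueError(f"illegal movement label {entry['movement']!r}")
        if entry["load"] not in LOADS:
            raise ValueError(f"illegal load label {entry['load']!r}")
        rec = EmgRecording(
            data=np.load(directory / entry["file"]),
            fs=entry["fs"],
            channel_names=tuple(entry["channel_names"]),
            filtered=entry["filtered"],
            normalized=entry["normalized"],
        )
        trials.append(
            Trial(
                recording=rec,
                movement=entry["movement"],
                load=entry["load"],
                subject=entry["subject"],
                repetition=entry["repetition"],
                trial_id=entry["trial_id"],
                protocol=ProtocolSpec(**entry["protocol"]),
            )
        )
    return trials


# --------------------------------------------------------------------------
# pipeline: trials -> windows -> dataset
# --------------------------------------------------------------------------

def preprocess_trial(
    trial: Trial,
    apply_normalize: bool = False,
    zero_phase: bool = False,
) -> EmgRecording:
    """Filter a trial and cut out its trimmed active segment.

    Chain: 50 Hz notch -> 20-450 Hz band-pass -> active (motion+hold)
    slice -> trim 200 ms from each end -> optional per-trial z-score.
    Normalization is off by default: the experiments need the amplitude
    scale for the load stage and for the load-shift phenomenon itself.
    Recordings already flagged as filtered are not re-filtered, and
    recordings already at the trimmed effective length are not re-cut, so
    containers written by the preprocess stage pass through unchanged.
    """
    rec = trial.recording
    if not rec.filtered:
        rec = notch_filter(rec, zero_phase=zero_phase)
        rec = bandpass_filter(rec, zero_phase=zero_phase)
    n_effective = int(round(trial.protocol.effective_s * rec.fs))
    if rec.n_samples != n_effective:
        start, stop = trial.protocol.active_slice()
        rec = rec.slice_samples(start, stop)
        rec = trim_trial(rec, trial.protocol.trim_ms)
    if apply_normalize and not rec.normalized:
        rec = normalize(rec)
    return rec


@dataclass
class WindowDataset:
    """Stacked per-window arrays for the experiments.

    ``tensors`` (n, 20, N, C) feature tensors; ``rms`` (n, C) per-channel
    RMS of the filtered window; ``raw`` (n, C, samples) filtered samples;
    ``y_move``/``y_load`` integer labels indexing MOVEMENTS/LOADS.
    """

    tensors: np.ndarray
    rms: np.ndarray
    raw: np.ndarray
    y_move: np.ndarray
    y_load: np.ndarray
    subject: np.ndarray
    trial_id: np.ndarray
    feature_names: tuple

    def __len__(self) -> int:
        return len(self.y_move)

    @property
    def load_labels(self) -> np.ndarray:
        return np.array([LOADS[i] for i in self.y_load])

    def subset(self, idx) -> "WindowDataset":
        idx = np.asarray(idx)
        return WindowDataset(
            tensors=self.tensors[idx],
            rms=self.rms[idx],
            raw=self.raw[idx],
            y_move=self.y_move[idx],
            y_load=self.y_load[idx],
            subject=self.subject[idx],
            trial_id=self.trial_id[idx],
            feature_names=self.feature_names,
        )


def build_window_dataset(
    trials: list[Trial],
    wspec: WindowingSpec = WindowingSpec(),
    fspec: FeatureSpec = FeatureSpec(),
    apply_normalize: bool = False,
    zero_phase: bool = False,
) -> WindowDataset:
    """Preprocess, segment and featurize every trial.

    Windows never span trial boundaries. RMS vectors are always computed
    on the filtered (un-normalized) samples; feature tensors follow
    ``apply_normalize``.
    """
    from .load_stage import window_rms

    tensors, rms_rows, raws = [], [], []
    y_move, y_load, subject, trial_id = [], [], [], []
    for t in trials:
        filtered = preprocess_trial(t, apply_normalize=False, zero_phase=zero_phase)
        source = normalize(filtered) if apply_normalize else filtered
        f_windows = segment_large(
            filtered, wspec, movement=t.movement, load=t.load,
            subject=t.subject, trial_id=t.trial_id,
        )
        s_windows = (
            segment_large(
                source, wspec, movement=t.movement, load=t.load,
                subject=t.subject, trial_id=t.trial_id,
            )
            if apply_normalize
            else f_windows
        )
        for fw, sw in zip(f_windows, s_windows):
            rms_rows.append(window_rms(fw).rms)
            raws.append(fw.data)
            tensors.append(extract_tensor(sw, wspec, fspec).values)
            y_move.append(MOVEMENTS.index(t.movement))
            y_load.append(LOADS.index(t.load))
            subject.append(t.subject)
            trial_id.append(t.trial_id)
    return WindowDataset(
        tensors=np.array(tensors),
        rms=np.array(rms_rows),
        raw=np.array(raws),
        y_move=np.array(y_move, dtype=int),
        y_load=np.array(y_load, dtype=int),
        subject=np.array(subject, dtype=int),
        trial_id=np.array(trial_id, dtype=int),
        feature_names=fspec.names,
    )


# --------------------------------------------------------------------------
# splitting and metrics
# --------------------------------------------------------------------------

def _stratified_counts(strata: np.ndarray, n_train: int) -> dict:
    """Per-stratum training counts summing exactly to ``n_train``."""
    labels, counts = np.unique(strata, return_counts=True)
    exact = counts * n_train / counts.sum()
    base = np.floor(exact).astype(int)
    short = n_train - base.sum()
    order = np.argsort(-(exact - base))
    base[order[:short]] += 1
    return dict(zip(labels.tolist(), base.tolist()))


def split_dataset(windows, ratio: float = 0.8, seed: int = 0, stratify=None):
    """Random train/test split with training count = floor(ratio * total).

    ``windows`` may be a :class:`WindowDataset` (split via ``subset``) or
    any sequence. ``stratify`` optionally gives per-window labels whose
    proportions are preserved. The two parts are disjoint and exhaustive.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie in (0, 1)")
    n = len(windows)
    if n < 2:
        raise ValueError("need at least 2 windows to split")
    n_train = int(ratio * n)
    rng = np.random.default_rng(seed)
    if stratify is None:
        perm = rng.permutation(n)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
    else:
        strata = np.asarray(stratify)
        quota = _stratified_counts(strata, n_train)
        train_parts, test_parts = [], []
        for label in np.unique(strata):
            idx = rng.permutation(np.nonzero(strata == label)[0])
            k = quota[label.item() if hasattr(label, "item") else label]
            train_parts.append(idx[:k])
            test_parts.append(idx[k:])
        train_idx = rng.permutation(np.concatenate(train_parts))
        test_idx = rng.permutation(np.concatenate(test_parts))
    if hasattr(windows, "subset"):
        return windows.subset(train_idx), windows.subset(test_idx)
    return [windows[i] for i in train_idx], [windows[i] for i in test_idx]


@dataclass
class EvalReport:
    """Movement-classification metrics.

    Accuracies are percentages with the tables' conventions: overall =
    100 * trace(confusion) / total; per-load accuracy conditions on the
    *true* load of each test window.
    """

    confusion: np.ndarray
    class_names: tuple
    overall_accuracy: float
    per_load_accuracy: dict | None = None
    n_samples: int = 0

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "class_names": list(self.class_names),
            "overall_accuracy": self.overall_accuracy,
            "per_load_accuracy": self.per_load_accuracy,
            "n_samples": self.n_samples,
        }


def evaluate(predictions, truths, loads=None) -> EvalReport:
    """Confusion matrix and accuracy summary of movement predictions."""
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    if predictions.shape != truths.shape:
        raise ValueError("predictions and truths must have equal length")
    if predictions.size == 0:
        raise ValueError("empty evaluation input")
    labels = np.arange(len(MOVEMENTS))
    cm = confusion_matrix(truths, predictions, labels=labels)
    overall = 100.0 * np.trace(cm) / cm.sum()
    per_load = None
    if loads is not None:
        loads = np.asarray(loads)
        per_load = {}
        for i, name in enumerate(LOADS):
            mask = loads == i
            if mask.any():
                per_load[name] = float(
                    100.0 * np.mean(predictions[mask] == truths[mask])
                )
    return EvalReport(
        confusion=cm,
        class_names=MOVEMENTS,
        overall_accuracy=float(overall),
        per_load_accuracy=per_load,
        n_samples=int(truths.size),
    )


def crossval_scores(
    make_model, X, y, n_folds: int = 5, seed: int = 0
) -> np.ndarray:
    """Stratified k-fold validation accuracies (percent) within a training set."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = []
    for tr, va in skf.split(X, y):
        model = make_model()
        model.fit(X[tr], y[tr])
        scores.append(100.0 * np.mean(model.predict(X[va]) == y[va]))
    return np.array(scores)


# --------------------------------------------------------------------------
# experiments
# --------------------------------------------------------------------------

@dataclass
class OneStepResult:
    """3x3 train-load x test-load accuracy matrix and its summaries."""

    matrix: np.ndarray  # percent, rows = training load, cols = testing load
    intraload_mean: float
    intraload_std: float
    interload_mean: float
    interload_std: float
    overall_mean: float

    def to_dict(self) -> dict:
        return {
            "matrix": self.matrix.tolist(),
            "loads": list(LOADS),
            "intraload_mean": self.intraload_mean,
            "intraload_std": self.intraload_std,
            "interload_mean": self.interload_mean,
            "interload_std": self.interload_std,
            "overall_mean": self.overall_mean,
        }


def _summarize_matrix(matrix: np.ndarray) -> OneStepResult:
    diag = np.diag(matrix)
    off = matrix[~np.eye(3, dtype=bool)]
    return OneStepResult(
        matrix=matrix,
        intraload_mean=float(diag.mean()),
        intraload_std=float(diag.std(ddof=1)),
        interload_mean=float(off.mean()),
        interload_std=float(off.std(ddof=1)),
        overall_mean=float(matrix.mean()),
    )


def _split_per_load(dataset: WindowDataset, ratio: float, seed: int):
    """8:2 split within each load level, stratified by movement."""
    splits = {}
    for i, load in enumerate(LOADS):
        idx = np.nonzero(dataset.y_load == i)[0]
        if idx.size == 0:
            raise ValueError(f"dataset has no windows under load {load!r}")
        sub = dataset.subset(idx)
        splits[load] = split_dataset(
            sub, ratio=ratio, seed=seed + i, stratify=sub.y_move
        )
    return splits


def _train_per_load_models(
    splits, spec: ModelSpec, epochs: int, batch_size: int, lr: float, seed: int
):
    models = {}
    for i, load in enumerate(LOADS):
        train, _ = splits[load]
        model = CnnLstmClassifier(
            spec=spec, epochs=epochs, batch_size=batch_size,
            learning_rate=lr, random_state=seed + 100 + i,
        )
        model.fit(train.tensors, train.y_move)
        models[load] = model
    return models


def run_one_step_experiment(
    dataset: WindowDataset,
    seed: int = 0,
    epochs: int = 30,
    batch_size: int = 256,
    learning_rate: float = 0.001,
    spec: ModelSpec | None = None,
    ratio: float = 0.8,
    _shared=None,
) -> OneStepResult:
    """Train one movement model per load; test each under all three loads.

    Cell (i, j) of the result is the accuracy (percent) of the model
    trained under load i on the held-out windows of load j.
    """
    if spec is None:
        spec = ModelSpec(n_features=len(dataset.feature_names))
    if _shared is not None:
        splits, models = _shared
    else:
        splits = _split_per_load(dataset, ratio, seed)
        models = _train_per_load_models(
            splits, spec, epochs, batch_size, learning_rate, seed
        )
    matrix = np.zeros((3, 3))
    for i, train_load in enumerate(LOADS):
        for j, test_load in enumerate(LOADS):
            _, test = splits[test_load]
            pred = models[train_load].predict(test.tensors)
            matrix[i, j] = 100.0 * np.mean(pred == test.y_move)
    return _summarize_matrix(matrix)


def run_two_step_experiment(
    dataset: WindowDataset,
    seed: int = 0,
    epochs: int = 30,
    batch_size: int = 256,
    learning_rate: float = 0.001,
    spec: ModelSpec | None = None,
    ratio: float = 0.8,
    n_trees: int = 200,
    oracle_load: bool = False,
    _shared=None,
) -> EvalReport:
    """End-to-end two-step evaluation on held-out windows.

    Trains the RMS load classifier on the pooled training windows and a
    movement model per load on that load's training windows, then routes
    every test window through predicted load (or the true load when
    ``oracle_load``) to the matching movement model.
    """
    if spec is None:
        spec = ModelSpec(n_features=len(dataset.feature_names))
    if _shared is not None:
        splits, models = _shared
    else:
        splits = _split_per_load(dataset, ratio, seed)
        models = _train_per_load_models(
            splits, spec, epochs, batch_size, learning_rate, seed
        )
    train_all = [splits[l][0] for l in LOADS]
    test_all = [splits[l][1] for l in LOADS]
    rms_train = np.concatenate([t.rms for t in train_all])
    load_train = np.concatenate([t.load_labels for t in train_all])
    load_clf = LoadClassifier(n_trees=n_trees, random_state=seed).fit(
        rms_train, load_train
    )
    clf = TwoStepClassifier(load_clf, models)

    tensors = np.concatenate([t.tensors for t in test_all])
    rms = np.concatenate([t.rms for t in test_all])
    y_move = np.concatenate([t.y_move for t in test_all])
    y_load = np.concatenate([t.y_load for t in test_all])
    if oracle_load:
        pred = clf.predict(tensors, loads=np.array([LOADS[i] for i in y_load]))
    else:
        pred = clf.predict(tensors, rms=rms)
    return evaluate(pred, y_move, loads=y_load)


def run_full_comparison(
    dataset: WindowDataset,
    seed: int = 0,
    epochs: int = 30,
    batch_size: int = 256,
    learning_rate: float = 0.001,
    spec: ModelSpec | None = None,
    ratio: float = 0.8,
) -> dict:
    """One-step matrix and two-step report on shared splits and models.

    The per-load movement models are trained once and reused by both
    protocols, so the comparison differs only in routing.
    """
    if spec is None:
        spec = ModelSpec(n_features=len(dataset.feature_names))
    splits = _split_per_load(dataset, ratio, seed)
    models = _train_per_load_models(splits, spec, epochs, batch_size, learning_rate, seed)
    shared = (splits, models)
    one = run_one_step_experiment(dataset, seed=seed, spec=spec, _shared=shared)
    two = run_two_step_experiment(
        dataset, seed=seed, spec=spec, ratio=ratio, _shared=shared
    )
    two_oracle = run_two_step_experiment(
        dataset, seed=seed, spec=spec, ratio=ratio, oracle_load=True, _shared=shared
    )
    return {"one_step": one, "two_step": two, "two_step_oracle": two_oracle}


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

def load_config(path=None) -> dict:
    """Default configuration, optionally overridden by a YAML file.

    The file may specify any subset of the sections/keys of
    :func:`default_config`; unknown keys are rejected.
    """
    import yaml

    cfg = default_config()
    if path is None:
        return cfg
    overrides = yaml.safe_load(Path(path).read_text()) or {}
    for section, values in overrides.items():
        if section not in cfg:
            raise KeyError(f"unknown config section {section!r}")
        for key, value in values.items():
            if key not in cfg[section]:
                raise KeyError(f"unknown config key {section}.{key}")
            cfg[section][key] = value
    return cfg


def default_config() -> dict:
    """Every pipeline constant in one overridable mapping."""
    return {
        "windowing": {"large_ms": 210, "large_slide_ms": 120,
                      "small_ms": 20, "small_slide_ms": 10},
        "filters": {"notch_hz": 50, "notch_q": 30,
                    "band_low_hz": 20, "band_high_hz": 450, "band_order": 4},
        "features": {"threshold_uv": 50, "candidates": list(FeatureSpec().names)},
        "network": {"conv_filters": 32, "conv1_kernel": 3, "conv2_kernel": 2,
                    "pool": 2, "lstm_units": 50, "dense_units": 100,
                    "n_classes": 6, "dropout": 0.6},
        "training": {"learning_rate": 0.001, "batch_size": 256, "epochs": 100,
                     "split_ratio": 0.8, "cv_folds": 5},
        "load_stage": {"n_trees": 200},
        "boruta": {"max_iter": 100, "alpha": 0.05, "n_trees": 200},
    }
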