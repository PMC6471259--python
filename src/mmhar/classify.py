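"""Per-modality classifiers, majority-vote decision fusion, and evaluation.

One classifier is trained per modality: the depth camera's T x 75 projection
sequences, the gyroscopes' M x 36 windowed statistics, and the
accelerometers' M x 36 windowed statistics.  The sequence model is an LSTM
(32 hidden units, dense/sigmoid head of size 10); the baseline is an SVM on
the fully concatenated feature vector.  The three per-modality decisions are
fused at decision level by majority vote; a three-way disagreement is broken
by the largest top-1 score margin, with a fixed fallback priority
ACCEL > DEPTH > GYRO.

Evaluation follows a stratified 30 % hold-out: per class, 30 % of trials go
to test, the rest to training; reports carry the 10x10 confusion matrix,
per-class accuracies, and their mean ("average accuracy", in percent).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .inertial import WindowingConfig, flatten_inertial, inertial_features
from .nn import LSTMClassifier
from .segmentation import SegmentationConfig, segment_trial
from .skeleton import feature_cube, flatten_skeleton
from .types import BehaviorLabel, Trial, ValidationError

__all__ = [
    "ModalityId",
    "ClassifierConfig",
    "ModalityPrediction",
    "FusionResult",
    "EvaluationReport",
    "ModalityClassifier",
    "train_modality_classifier",
    "majority_vote",
    "split_trials",
    "extract_features",
    "evaluate",
]

N_CLASSES = len(BehaviorLabel)


class ModalityId(enum.IntEnum):
    DEPTH = 0
    GYRO = 1
    ACCEL = 2


#: Static tie-break priority for three-way disagreements, most reliable first.
FALLBACK_ORDER = (ModalityId.ACCEL, ModalityId.DEPTH, ModalityId.GYRO)


@dataclass(frozen=True)
class ClassifierConfig:
    model_kind: str = "lstm"  # "lstm" | "svm"
    hidden_units: int = 32
    n_classes: int = N_CLASSES
    epochs: int = 500
    learning_rate: float = 1e-3
    batch_size: int = 32
    output: str = "sigmoid"
    svm_kernel: str = "linear"
    svm_C: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.model_kind not in ("lstm", "svm"):
            raise ValidationError(f"unknown model kind {self.model_kind!r}")
        if self.hidden_units < 1:
            raise ValidationError("hidden_units must be >= 1")
        if self.n_classes != N_CLASSES:
            raise ValidationError(f"n_classes must equal {N_CLASSES}")


@dataclass(frozen=True)
class ModalityPrediction:
    modality: ModalityId
    label: BehaviorLabel
    scores: np.ndarray  # (10,) in [0, 1]

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float)
        if scores.shape != (N_CLASSES,) or not np.all(np.isfinite(scores)):
            raise ValidationError("scores must be a finite 10-vector")
        object.__setattr__(self, "scores", scores)
        if int(self.label) != int(np.argmax(scores)):
            raise ValidationError("label must be the argmax of scores")


@dataclass(frozen=True)
class FusionResult:
    label: BehaviorLabel
    votes: Dict[BehaviorLabel, int]
    tiebreak_used: bool


@dataclass
class EvaluationReport:
    """Confusion matrix (rows true, columns predicted) and accuracy summary."""

    confusion: np.ndarray  # (10, 10) counts
    per_class_accuracy: np.ndarray  # (10,) in [0, 1]
    average_accuracy: float  # percent, mean of per-class accuracies
    overall_accuracy: float  # percent, fraction of correct predictions
    split_seed: int

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "per_class_accuracy": self.per_class_accuracy.tolist(),
            "average_accuracy": self.average_accuracy,
            "overall_accuracy": self.overall_accuracy,
            "split_seed": self.split_seed,
        }


class ModalityClassifier:
    """Standardization + sequence model (LSTM) or flat-vector model (SVM).

    Sequences are z-scored per feature dimension with training-set statistics.
    The SVM consumes the fully concatenated per-trial vector and converts
    one-vs-rest decision values to [0, 1] scores by a softmax.
    """

    def __init__(self, modality: ModalityId, config: ClassifierConfig):
        self.modality = ModalityId(modality)
        self.config = config
        self._model = None
        self._mu: Optional[np.ndarray] = None
        self._sd: Optional[np.ndarray] = None

    def fit(self, sequences: np.ndarray, labels: Sequence[BehaviorLabel]) -> "ModalityClassifier":
        X = np.asarray(sequences, dtype=float)
        if X.ndim != 3:
            raise ValidationError(f"expected (n, steps, dim) sequences, got shape {X.shape}")
        y = np.asarray([int(l) for l in labels], dtype=int)
        if len(X) != len(y):
            raise ValidationError("features and labels length mismatch")
        if len(np.unique(y)) < 2:
            raise ValidationError("need at least 2 classes to train")
        self._mu = X.reshape(-1, X.shape[2]).mean(axis=0)
        sd = X.reshape(-1, X.shape[2]).std(axis=0)
        self._sd = np.where(sd > 0, sd, 1.0)
        Xn = (X - self._mu) / self._sd
        cfg = self.config
        if cfg.model_kind == "lstm":
            self._model = LSTMClassifier(
                n_features=X.shape[2],
                n_classes=cfg.n_classes,
                hidden_units=cfg.hidden_units,
                epochs=cfg.epochs,
                learning_rate=cfg.learning_rate,
                batch_size=cfg.batch_size,
                output=cfg.output,
                seed=cfg.seed,
            ).fit(Xn, y)
        else:
            flat = Xn.reshape(len(X), -1)
            self._model = make_pipeline(
                StandardScaler(),
                SVC(
                    kernel=cfg.svm_kernel,
                    C=cfg.svm_C,
                    decision_function_shape="ovr",
                    random_state=cfg.seed,
                ),
            ).fit(flat, y)
            self._svm_classes = self._model[-1].classes_
        return self

    def decision_scores(self, sequences: np.ndarray) -> np.ndarray:
        if self._model is None:
            raise ValidationError("classifier is not fitted")
        X = (np.asarray(sequences, dtype=float) - self._mu) / self._sd
        if self.config.model_kind == "lstm":
            return self._model.decision_scores(X)
        dec = self._model.decision_function(X.reshape(len(X), -1))
        if dec.ndim == 1:  # two trained classes
            dec = np.column_stack([-dec, dec])
        full = np.full((len(X), N_CLASSES), -np.inf)
        full[:, self._svm_classes] = dec
        m = full - full.max(axis=1, keepdims=True)
        e = np.where(np.isfinite(m), np.exp(m), 0.0)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, sequences: np.ndarray) -> List[ModalityPrediction]:
        scores = self.decision_scores(sequences)
        return [
            ModalityPrediction(self.modality, BehaviorLabel(int(s.argmax())), s) for s in scores
        ]

    def predict_labels(self, sequences: np.ndarray) -> np.ndarray:
        return self.decision_scores(sequences).argmax(axis=1)


def train_modality_classifier(
    sequences: np.ndarray,
    labels: Sequence[BehaviorLabel],
    config: ClassifierConfig,
    modality: ModalityId = ModalityId.DEPTH,
) -> ModalityClassifier:
    """Fit one per-modality classifier on (n, steps, dim) feature sequences."""
    return ModalityClassifier(modality, config).fit(sequences, labels)


def majority_vote(preds: Sequence[ModalityPrediction]) -> FusionResult:
    """Fuse the three per-modality decisions.

    A label backed by at least two modalities wins outright.  If all three
    disagree, the modality with the largest top-1 score margin (best minus
    second-best score) decides; exact margin ties fall back to the static
    priority ACCEL > DEPTH > GYRO.
    """
    if len(preds) != 3 or {p.modality for p in preds} != set(ModalityId):
        raise ValidationError("majority_vote needs exactly one prediction per modality")
    by_mod = {p.modality: p for p in preds}
    votes: Dict[BehaviorLabel, int] = {}
    for p in preds:
        votes[p.label] = votes.get(p.label, 0) + 1
    top_label, top_count = max(votes.items(), key=lambda kv: kv[1])
    if top_count >= 2:
        return FusionResult(label=top_label, votes=votes, tiebreak_used=False)
    margins = {}
    for mod, p in by_mod.items():
        s = np.sort(p.scores)[::-1]
        margins[mod] = s[0] - s[1]
    best = max(
        FALLBACK_ORDER,
        key=lambda mod: (margins[mod], -FALLBACK_ORDER.index(mod)),
    )
    return FusionResult(label=by_mod[best].label, votes=votes, tiebreak_used=True)


def split_trials(
    trials: Sequence[Trial],
    test_fraction: float = 0.3,
    seed: int = 0,
) -> Tuple[List[int], List[int]]:
    """Stratified hold-out: per class, round(test_fraction * n) trials to test.

    Returns (train_indices, test_indices); disjoint, exhaustive, reproducible
    by seed.
    """
    if not 0 < test_fraction < 1:
        raise ValidationError("test_fraction must be in (0, 1)")
    labels = []
    for t in trials:
        if t.label is None:
            raise ValidationError(f"trial {t.trial_id} is unlabeled")
        labels.append(int(t.label))
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx: List[int] = []
    test_idx: List[int] = []
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        if len(idx) < 2:
            raise ValidationError(f"class {BehaviorLabel(cls).name} has fewer than 2 trials")
        idx = rng.permutation(idx)
        n_test = int(round(test_fraction * len(idx)))
        test_idx.extend(idx[:n_test].tolist())
        train_idx.extend(idx[n_test:].tolist())
    return sorted(train_idx), sorted(test_idx)


def extract_features(
    trials: Sequence[Trial],
    seg_config: SegmentationConfig = SegmentationConfig(),
    win_config: WindowingConfig = WindowingConfig(),
    unit_basis: bool = True,
) -> Dict[ModalityId, np.ndarray]:
    """Segment every trial and compute the three per-modality feature arrays.

    Returns DEPTH (n, T, 75), GYRO (n, M, 36), ACCEL (n, M, 36).
    """
    depth, gyro, accel = [], [], []
    for trial in trials:
        segment = segment_trial(trial, seg_config)
        cube = feature_cube(
            trial.skeleton, segment, n_points=seg_config.resample_points, unit_basis=unit_basis
        )
        depth.append(flatten_skeleton(cube))
        g, a = inertial_features(trial, segment, win_config)
        gyro.append(flatten_inertial(g))
        accel.append(flatten_inertial(a))
    return {
        ModalityId.DEPTH: np.stack(depth),
        ModalityId.GYRO: np.stack(gyro),
        ModalityId.ACCEL: np.stack(accel),
    }


def _report(y_true: np.ndarray, y_pred: np.ndarray, split_seed: int) -> EvaluationReport:
    cm = confusion_matrix(y_true, y_pred, labels=list(range(N_CLASSES)))
    row = cm.sum(axis=1)
    per_class = np.divide(np.diag(cm), row, out=np.zeros(N_CLASSES), where=row > 0)
    return EvaluationReport(
        confusion=cm,
        per_class_accuracy=per_class,
        average_accuracy=float(per_class[row > 0].mean() * 100.0) if (row > 0).any() else 0.0,
        overall_accuracy=float((y_true == y_pred).mean() * 100.0),
        split_seed=split_seed,
    )


def evaluate(
    trials: Sequence[Trial],
    configs: Optional[Dict[ModalityId, ClassifierConfig]] = None,
    test_fraction: float = 0.3,
    seed: int = 0,
    seg_config: SegmentationConfig = SegmentationConfig(),
    win_config: WindowingConfig = WindowingConfig(),
    features: Optional[Dict[ModalityId, np.ndarray]] = None,
) -> Tuple[Dict[ModalityId, EvaluationReport], EvaluationReport]:
    """Full protocol: segment, featurize, stratified 30 % hold-out, train one
    classifier per modality, fuse decisions, and report confusion matrices.

    ``features`` may carry precomputed :func:`extract_features` output to
    avoid repeating the feature extraction.  Per-modality classifier seeds
    are derived from ``seed`` so the whole evaluation is deterministic.
    """
    if configs is None:
        configs = {m: ClassifierConfig() for m in ModalityId}
    if features is None:
        features = extract_features(trials, seg_config, win_config)
    labels = np.asarray([int(t.label) for t in trials])
    train_idx, test_idx = split_trials(trials, test_fraction, seed)
    y_train, y_test = labels[train_idx], labels[test_idx]

    reports: Dict[ModalityId, EvaluationReport] = {}
    test_preds: Dict[ModalityId, List[ModalityPrediction]] = {}
    for modality in ModalityId:
        cfg = configs[modality]
        cfg = replace(cfg, seed=int(np.random.SeedSequence([cfg.seed, int(modality)]).generate_state(1)[0] % (2**31)))
        clf = ModalityClassifier(modality, cfg).fit(features[modality][train_idx], y_train)
        preds = clf.predict(features[modality][test_idx])
        test_preds[modality] = preds
        reports[modality] = _report(y_test, np.asarray([int(p.label) for p in preds]), seed)

    fused = [
        int(majority_vote([test_preds[m][i] for m in ModalityId]).label)
        for i in range(len(test_idx))
    ]
    fusion_report = _report(y_test, np.asarray(fused), seed)
    return reports, fusion_report
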