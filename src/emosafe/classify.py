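"""Per-band KNN emotion classification and its evaluation machinery.

The classifier is deliberately simple: Euclidean k-nearest-neighbor voting
on z-scored (SampEn, band-PSD) features, with standardization fit on the
training split only.  Ties in the vote go to the class of the single
nearest neighbor.  Evaluation produces a 3x3 confusion matrix, per-class
true-positive rates, overall accuracy, one-vs-rest ROC curves (scores =
neighbor-vote fractions) and a 2-D principal-component projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .features import FeatureMatrix, SampEnParams, build_feature_matrix
from .preprocess import (
    EpochSet,
    FilterSpec,
    bandpass_filter,
    band_filter,
    baseline_correct,
    concat_epochs,
    notch_filter,
    segment_epochs,
)
from .recording import BANDS, STATES, BandDefinition, EEGRecording


class UndefinedROCError(ValueError):
    """Raised when a one-vs-rest ROC is requested for an absent class."""


@dataclass(frozen=True)
class KnnConfig:
    """KNN settings: neighbor count and (fixed) metric conventions."""

    k: int = 5

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")


@dataclass
class ClassificationReport:
    """Confusion accounting plus optional ROC curves for one classifier run."""

    classes: tuple[str, ...]
    confusion: np.ndarray  # rows = true, columns = predicted
    roc: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    auc: dict[str, float] = field(default_factory=dict)

    @property
    def class_n(self) -> np.ndarray:
        return self.confusion.sum(axis=1)

    @property
    def tp_rate(self) -> np.ndarray:
        """Per-class percentage of true samples correctly classified."""
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.diag(self.confusion) / self.class_n
        return 100.0 * rate

    @property
    def overall_accuracy(self) -> float:
        """Percent correct over all samples (100 * trace / total)."""
        return 100.0 * np.trace(self.confusion) / self.confusion.sum()

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "tp_rate": [round(v, 6) for v in self.tp_rate],
            "overall_accuracy": round(self.overall_accuracy, 6),
            "auc": {c: round(v, 6) for c, v in self.auc.items()},
            "roc": {
                c: [(round(f, 6), round(t, 6)) for f, t in pts]
                for c, pts in self.roc.items()
            },
        }


def _standardize(train_x: np.ndarray, *others: np.ndarray):
    mu = train_x.mean(axis=0)
    sd = train_x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return tuple((x - mu) / sd for x in (train_x, *others))


def _as_xy(data, labels=None):
    if isinstance(data, FeatureMatrix):
        return data.values, list(data.labels)
    return np.asarray(data, dtype=float), list(labels) if labels is not None else None


def knn_predict(
    train,
    test,
    config: KnnConfig = KnnConfig(),
    train_labels=None,
):
    """Majority-vote KNN with vote-fraction scores.

    ``train``/``test`` are FeatureMatrix objects (labels carried inside) or
    plain arrays, in which case ``train_labels`` must be supplied.  Features
    are z-scored with statistics fit on the training set.  Returns
    ``(predicted_labels, scores, classes)`` where ``scores[i, c]`` is the
    fraction of the k neighbors of test row i belonging to ``classes[c]``.
    """
    train_x, tr_labels = _as_xy(train, train_labels)
    test_x, _ = _as_xy(test)
    if tr_labels is None:
        raise ValueError("training labels are required")
    if len(train_x) == 0:
        raise ValueError("training set is empty")
    if config.k > len(train_x):
        raise ValueError(f"k={config.k} exceeds training-set size {len(train_x)}")
    if train_x.shape[1] != test_x.shape[1]:
        raise ValueError("train and test feature layouts differ")
    if not (np.all(np.isfinite(train_x)) and np.all(np.isfinite(test_x))):
        raise ValueError("non-finite feature values")

    classes = tuple(dict.fromkeys(tr_labels))  # first-appearance order
    class_idx = {c: i for i, c in enumerate(classes)}
    y = np.array([class_idx[lab] for lab in tr_labels])

    train_z, test_z = _standardize(train_x, test_x)
    # full pairwise distances; problem sizes here are hundreds of rows
    d2 = (
        (test_z**2).sum(axis=1)[:, None]
        + (train_z**2).sum(axis=1)[None, :]
        - 2.0 * test_z @ train_z.T
    )
    order = np.argsort(d2, axis=1, kind="stable")[:, : config.k]

    predictions: list[str] = []
    scores = np.zeros((len(test_z), len(classes)))
    for i, nbrs in enumerate(order):
        votes = np.bincount(y[nbrs], minlength=len(classes))
        scores[i] = votes / config.k
        best = votes.max()
        tied = {c for c in range(len(classes)) if votes[c] == best}
        if len(tied) == 1:
            winner = tied.pop()
        else:
            # tie rule: the tied class owning the nearest neighbor wins
            winner = next(int(y[j]) for j in nbrs if int(y[j]) in tied)
        predictions.append(classes[winner])
    return predictions, scores, classes


def select_k(
    features: FeatureMatrix,
    candidates: list[int],
    folds: int = 5,
    seed: int = 0,
    ) -> tuple[int, dict[int, float]]:
    """Choose k by stratified cross-validated accuracy (smallest k on ties)."""
    if not candidates:
        raise ValueError("candidate list is empty")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = np.asarray(features.labels)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(features.values, y))
    min_train = min(len(tr) for tr, _ in splits)
    bad = [k for k in candidates if k > min_train]
    if bad:
        raise ValueError(
            f"candidates {bad} exceed the smallest training fold ({min_train})"
        )
    accuracy: dict[int, float] = {}
    for k in candidates:
        correct = 0
        for tr, te in splits:
            pred, _, _ = knn_predict(
                features.values[tr],
                features.values[te],
                KnnConfig(k=k),
                train_labels=list(y[tr]),
            )
            correct += int(np.sum(np.asarray(pred) == y[te]))
        accuracy[k] = correct / len(y)
    best = max(sorted(candidates), key=lambda k: (accuracy[k], -k))
    return best, accuracy


def evaluate(
    true_labels, predicted_labels, classes: tuple[str, ...] | None = None
) -> ClassificationReport:
    """Confusion matrix, per-class TP rates and overall accuracy."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("true and predicted label lists differ in length")
    if classes is None:
        seen = set(true_labels) | set(predicted_labels)
        classes = STATES if seen <= set(STATES) else tuple(sorted(seen))
    idx = {c: i for i, c in enumerate(classes)}
    unknown = [lab for lab in true_labels + predicted_labels if lab not in idx]
    if unknown:
        raise ValueError(f"labels outside the class alphabet {classes}: {unknown[:5]}")
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        confusion[idx[t], idx[p]] += 1
    return ClassificationReport(classes=tuple(classes), confusion=confusion)


def one_vs_rest_roc(
    true_labels, scores: np.ndarray, classes: tuple[str, ...]
) -> tuple[dict[str, list[tuple[float, float]]], dict[str, float]]:
    """ROC curve and trapezoidal AUC per class, one-vs-rest.

    ``scores[i, c]`` is the classifier's score for class ``classes[c]`` on
    sample i (here: neighbor-vote fractions, in [0, 1]).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != len(classes):
        raise ValueError("scores must be (n_samples, n_classes)")
    if scores.min() < 0 or scores.max() > 1:
        raise ValueError("scores must lie in [0, 1]")
    y = np.asarray(true_labels)
    roc: dict[str, list[tuple[float, float]]] = {}
    auc: dict[str, float] = {}
    for ci, c in enumerate(classes):
        pos = y == c
        if pos.all() or not pos.any():
            raise UndefinedROCError(
                f"ROC for class {c!r} is undefined: positives and negatives "
                "are both required"
            )
        fpr, tpr, _ = roc_curve(pos, scores[:, ci], drop_intermediate=False)
        roc[c] = list(zip(fpr.tolist(), tpr.tolist()))
        auc[c] = float(np.trapezoid(tpr, fpr))
    return roc, auc


def project_2d(features: FeatureMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Top-2 principal-component projection of the z-scored features.

    Returns ``(coords, components)`` with orthonormal component axes.
    """
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    if x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("projection needs at least 3 rows and 2 columns")
    (z,) = _standardize(x)
    if np.linalg.matrix_rank(z - z.mean(axis=0)) < 2:
        raise ValueError("degenerate projection: feature matrix has rank < 2")
    pca = PCA(n_components=2)
    coords = pca.fit_transform(z)
    return coords, pca.components_


@dataclass
class BandComparisonResult:
    """Per-band accuracy table plus the full report and features per band."""

    table: pd.DataFrame
    reports: dict[str, ClassificationReport]
    features: dict[str, FeatureMatrix]
    chosen_k: int


def _cross_validated_predictions(
    features: FeatureMatrix, config: KnnConfig, folds: int, seed: int, split: str
):
    y = np.asarray(features.labels)
    pred = np.empty(len(y), dtype=object)
    classes = tuple(dict.fromkeys(features.labels))
    scores = np.zeros((len(y), len(classes)))
    if split == "epoch":
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = skf.split(features.values, y)
    elif split == "subject":
        sources = np.asarray(features.meta.get("source_ids", [""] * len(y)))
        splits = (
            (np.flatnonzero(sources != s), np.flatnonzero(sources == s))
            for s in dict.fromkeys(sources)
        )
    else:
        raise ValueError(f"unknown split mode {split!r}")
    for tr, te in splits:
        p, s, cls = knn_predict(
            features.values[tr],
            features.values[te],
            config,
            train_labels=list(y[tr]),
        )
        pred[te] = p
        col = {c: i for i, c in enumerate(cls)}
        for c in classes:
            if c in col:
                scores[te, classes.index(c)] = s[:, col[c]]
    return list(pred), scores, classes


def run_band_comparison(
    recordings: list[EEGRecording],
    bands: list[BandDefinition] | None = None,
    config: KnnConfig = KnnConfig(),
    filter_spec: FilterSpec = FilterSpec(),
    sampen: SampEnParams = SampEnParams(),
    channels: tuple[str, ...] = ("T7", "T8"),
    window_length: float = 1.0,
    folds: int = 5,
    seed: int = 0,
    split: str = "epoch",
    k_candidates: list[int] | None = None,
) -> BandComparisonResult:
    """Full per-band pipeline: preprocess, extract features, cross-validate.

    Each recording is baseline-corrected, broadband-filtered and notched;
    for every analysis band the conditioned recordings are band-filtered,
    epoched and reduced to (SampEn, band-PSD) features, and a KNN classifier
    is cross-validated.  If ``k_candidates`` is given, k is selected once on
    the first band's features and reused everywhere.
    """
    if bands is None:
        bands = list(BANDS.values())
    labels_present = {rec.state_label for rec in recordings}
    if len(labels_present) < 2:
        raise ValueError("band comparison requires recordings from >= 2 classes")

    conditioned = []
    for rec in recordings:
        out = baseline_correct(rec)
        out = bandpass_filter(out, filter_spec)
        out = notch_filter(out, filter_spec.notch_freq, filter_spec.notch_bandwidth)
        conditioned.append(out)

    reports: dict[str, ClassificationReport] = {}
    feats: dict[str, FeatureMatrix] = {}
    rows = []
    chosen_k = config.k
    for bi, band in enumerate(bands):
        try:
            per_rec: list[EpochSet] = []
            for i, rec in enumerate(conditioned):
                narrow = band_filter(rec, band.f_lo, band.f_hi)
                per_rec.append(
                    segment_epochs(narrow, window_length, source_id=f"rec{i}")
                )
            epochs = concat_epochs(per_rec)
            fm = build_feature_matrix(epochs, channels, band, sampen)
            fm.meta["source_ids"] = list(epochs.source_ids)
            if bi == 0 and k_candidates:
                chosen_k, _ = select_k(fm, k_candidates, folds=folds, seed=seed)
            cfg = KnnConfig(k=chosen_k)
            pred, scores, classes = _cross_validated_predictions(
                fm, cfg, folds, seed, split
            )
            report = evaluate(fm.labels, pred, classes=classes)
            try:
                report.roc, report.auc = one_vs_rest_roc(fm.labels, scores, classes)
            except UndefinedROCError:
                pass
        except Exception as exc:
            raise type(exc)(f"band {band.name!r}: {exc}") from exc
        reports[band.name] = report
        feats[band.name] = fm
        rows.append(
            {
                "band": band.name,
                "f_lo": band.f_lo,
                "f_hi": band.f_hi,
                "accuracy_pct": report.overall_accuracy,
                **{
                    f"tp_{c}_pct": report.tp_rate[j]
                    for j, c in enumerate(report.classes)
                },
            }
        )
    table = pd.DataFrame(rows)
    return BandComparisonResult(
        table=table, reports=reports, features=feats, chosen_k=chosen_k
    )
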