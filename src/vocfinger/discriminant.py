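"""Shared classification machinery: Fisher LDA, KNN, leave-one-out evaluation,
the chance-accuracy null model, and per-class / binary reporting.

Everything here is deterministic: the LDA eigen-sign convention is fixed
(first nonzero loading positive) and KNN tie-breaking never depends on the
order in which training points are supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.linalg

from .io_formats import GroupLabel

__all__ = [
    "LdaModel",
    "ChanceNull",
    "ClassificationReport",
    "LoocvConfig",
    "fit_lda",
    "project",
    "knn_classify",
    "loocv",
    "chance_null",
    "permutation_null",
    "collapse_binary",
]

DEFAULT_REGULARIZATION = 1e-6
#: label treated as the positive class for the binary (BAM vs non-BAM) collapse
BINARY_POSITIVE = GroupLabel.BAD.value


def _as_label_array(labels: Sequence) -> np.ndarray:
    return np.array([str(lab) for lab in labels], dtype=object)


@dataclass
class LdaModel:
    """Fisher linear discriminant: projection into <= n_classes - 1 dimensions."""

    classes: list[str]
    class_means: np.ndarray  # (C, p)
    grand_mean: np.ndarray  # (p,)
    projection: np.ndarray  # (p, d), d <= C - 1
    regularization: float


@dataclass
class ChanceNull:
    """Accuracy expected from prior-proportional random reclassification.

    mean = sum_c p_c^2, sd = sqrt(mean * (1 - mean) / n).
    """

    mean: float
    sd: float
    n: int
    class_proportions: dict[str, float]

    @property
    def threshold(self) -> float:
        """The robustness bar: mean + 3 standard deviations."""
        return self.mean + 3.0 * self.sd


@dataclass
class ClassificationReport:
    classes: list[str]
    confusion: np.ndarray  # (C, C) counts, rows = truth
    per_class_accuracy: dict[str, float]
    overall_accuracy: float
    binary_accuracy: Optional[float]
    config_echo: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "confusion": self.confusion.tolist(),
            "per_class_accuracy": self.per_class_accuracy,
            "overall_accuracy": self.overall_accuracy,
            "binary_accuracy": self.binary_accuracy,
            "config": self.config_echo,
        }

    def to_text(self) -> str:
        width = max(len(c) for c in self.classes) + 2
        lines = ["Confusion matrix (rows = truth):"]
        lines.append(" " * width + "".join(f"{c:>{width}}" for c in self.classes))
        for i, c in enumerate(self.classes):
            lines.append(
                f"{c:>{width}}"
                + "".join(f"{int(v):>{width}}" for v in self.confusion[i])
            )
        lines.append("")
        for c in self.classes:
            lines.append(f"accuracy[{c}] = {self.per_class_accuracy[c]:.3f}")
        lines.append(f"overall accuracy = {self.overall_accuracy:.3f}")
        if self.binary_accuracy is not None:
            lines.append(
                f"binary ({BINARY_POSITIVE} vs rest) accuracy = "
                f"{self.binary_accuracy:.3f}"
            )
        return "\n".join(lines)


def fit_lda(
    features: np.ndarray,
    labels: Sequence,
    regularization: float = DEFAULT_REGULARIZATION,
) -> LdaModel:
    """Fit Fisher LDA, maximizing between-class over within-class variance.

    The pooled within-class covariance is regularized by adding
    ``regularization * mean(diag)`` to its diagonal, which keeps the
    generalized eigenproblem well-posed when selected-variable counts
    approach the sample count (or when features are duplicated).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D matrix (samples x variables)")
    y = _as_label_array(labels)
    if len(y) != X.shape[0]:
        raise ValueError("labels length must match the number of rows")
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("LDA requires at least 2 classes")
    n, p = X.shape
    means = np.empty((len(classes), p))
    Sw = np.zeros((p, p))
    for i, c in enumerate(classes):
        Xc = X[y == c]
        if Xc.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        means[i] = Xc.mean(axis=0)
        centered = Xc - means[i]
        Sw += centered.T @ centered
    Sw /= n - len(classes)
    if not np.any(Sw.diagonal() > 0) and np.allclose(X, X[0]):
        raise ValueError("all samples are identical; LDA is undefined")
    grand = X.mean(axis=0)
    Sb = np.zeros((p, p))
    for i, c in enumerate(classes):
        d = (means[i] - grand)[:, None]
        Sb += int(np.sum(y == c)) * (d @ d.T)
    lam = regularization * float(np.mean(Sw.diagonal()))
    if lam <= 0:
        lam = regularization
    evals, evecs = scipy.linalg.eigh(Sb, Sw + lam * np.eye(p))
    d = min(len(classes) - 1, p)
    order = np.argsort(evals)[::-1][:d]
    W = evecs[:, order]
    # deterministic sign: first loading of non-negligible magnitude is positive
    for j in range(W.shape[1]):
        col = W[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12 * np.abs(col).max())[0]
        if nz.size and col[nz[0]] < 0:
            W[:, j] = -col
    return LdaModel(
        classes=classes,
        class_means=means,
        grand_mean=grand,
        projection=W,
        regularization=regularization,
    )


def project(model: LdaModel, x: np.ndarray) -> np.ndarray:
    """Map samples into discriminant space (grand-mean centered)."""
    X = np.atleast_2d(np.asarray(x, dtype=float))
    return (X - model.grand_mean) @ model.projection


def knn_classify(
    train_coords: np.ndarray,
    train_labels: Sequence,
    query_coords: np.ndarray,
    k: int = 3,
) -> list[str]:
    """Majority-vote KNN with deterministic tie-breaking.

    Euclidean distance.  Ties in the vote are broken by the nearest neighbour
    among the tied classes; exact distance ties fall back to lexicographic
    class label, so the result never depends on training-set order.
    """
    Xtr = np.atleast_2d(np.asarray(train_coords, dtype=float))
    Xq = np.atleast_2d(np.asarray(query_coords, dtype=float))
    y = _as_label_array(train_labels)
    if Xtr.shape[0] == 0:
        raise ValueError("empty training set")
    if len(y) != Xtr.shape[0]:
        raise ValueError("train_labels length must match train_coords rows")
    if not (1 <= k <= Xtr.shape[0]):
        raise ValueError(f"k must be in [1, {Xtr.shape[0]}], got {k}")
    # lexicographic label codes make ordering independent of input order
    label_code = {c: i for i, c in enumerate(sorted(set(y)))}
    codes = np.array([label_code[c] for c in y])
    preds: list[str] = []
    diff = Xq[:, None, :] - Xtr[None, :, :]
    dists = np.sqrt(np.sum(diff * diff, axis=2))
    for qi in range(Xq.shape[0]):
        order = np.lexsort((codes, dists[qi]))  # by distance, then label
        top = order[:k]
        votes: dict[str, int] = {}
        for idx in top:
            votes[y[idx]] = votes.get(y[idx], 0) + 1
        best = max(votes.values())
        tied = sorted(c for c, v in votes.items() if v == best)
        if len(tied) == 1:
            preds.append(tied[0])
            continue
        # nearest neighbour among tied classes (order already distance-sorted)
        for idx in top:
            if y[idx] in tied:
                preds.append(y[idx])
                break
    return preds


@dataclass
class LoocvConfig:
    """Configuration of the leave-one-out loop.

    selection_thresholds, when given as ``(within, between)``, refits the
    scatter-statistic variable selection on each training fold (no leakage).
    groups assigns rows to biological samples; all rows of a group are held
    out together and vote by majority on the sample's label.
    """

    k: int = 3
    regularization: float = DEFAULT_REGULARIZATION
    use_lda: bool = True
    selection_thresholds: Optional[tuple[float, float]] = None
    selection_directions: tuple[str, str] = ("lt", "gt")
    groups: Optional[Sequence] = None

    def echo(self) -> dict:
        return {
            "k": self.k,
            "regularization": self.regularization,
            "use_lda": self.use_lda,
            "selection_thresholds": self.selection_thresholds,
            "selection_directions": list(self.selection_directions),
            "grouped": self.groups is not None,
        }


def _majority_vote(preds: list[str], nearest_dists: list[float]) -> str:
    votes: dict[str, int] = {}
    for p in preds:
        votes[p] = votes.get(p, 0) + 1
    best = max(votes.values())
    tied = sorted(c for c, v in votes.items() if v == best)
    if len(tied) == 1:
        return tied[0]
    # tie between replicates: trust the replicate with the closest neighbour
    candidates = [i for i, p in enumerate(preds) if p in tied]
    best_i = min(candidates, key=lambda i: (nearest_dists[i], preds[i]))
    return preds[best_i]


def loocv(
    features: np.ndarray,
    labels: Sequence,
    config: Optional[LoocvConfig] = None,
) -> ClassificationReport:
    """Leave-one-out reclassification with per-fold refitting.

    For every held-out biological sample the variable selection (if
    configured) and the LDA projection are refit on the remaining samples
    only; the held-out rows are then projected and KNN-classified.
    """
    from .faims import compute_scatter_stats, select_variables  # local: avoid cycle

    config = config or LoocvConfig()
    X = np.asarray(features, dtype=float)
    y = _as_label_array(labels)
    n = X.shape[0]
    if len(y) != n:
        raise ValueError("labels length must match feature rows")
    groups = (
        _as_label_array(config.groups)
        if config.groups is not None
        else np.array([f"row{i}" for i in range(n)], dtype=object)
    )
    if len(groups) != n:
        raise ValueError("groups length must match feature rows")
    # group -> row indices, preserving first-appearance order
    group_order: list[str] = []
    group_rows: dict[str, list[int]] = {}
    for i, g in enumerate(groups):
        if g not in group_rows:
            group_rows[g] = []
            group_order.append(g)
        group_rows[g].append(i)
    group_truth: dict[str, str] = {}
    for g, rows in group_rows.items():
        labs = set(y[rows])
        if len(labs) != 1:
            raise ValueError(f"group {g!r} mixes labels {sorted(labs)}")
        group_truth[g] = y[rows[0]]
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("LOOCV requires at least 2 classes")
    # every class must keep >= 2 biological samples after any single removal
    class_group_counts = {
        c: sum(1 for g in group_order if group_truth[g] == c) for c in classes
    }
    for c, cnt in class_group_counts.items():
        if cnt < 3:
            raise ValueError(
                f"class {c!r} has only {cnt} biological samples; leave-one-out "
                "would leave fewer than 2 for fitting"
            )
    truths: list[str] = []
    preds: list[str] = []
    for g in group_order:
        held = np.asarray(group_rows[g])
        mask = np.ones(n, dtype=bool)
        mask[held] = False
        Xtr, ytr = X[mask], y[mask]
        cols = slice(None)
        if config.selection_thresholds is not None:
            stats = compute_scatter_stats(Xtr, ytr)
            wt, bt = config.selection_thresholds
            idx = select_variables(
                stats,
                wt,
                bt,
                within_op=config.selection_directions[0],
                between_op=config.selection_directions[1],
            )
            if idx.size == 0:
                raise ValueError(
                    "variable selection produced an empty set on a training fold"
                )
            cols = idx
        Xtr_s = Xtr[:, cols]
        Xq_s = X[held][:, cols]
        if config.use_lda:
            model = fit_lda(Xtr_s, ytr, regularization=config.regularization)
            train_coords = project(model, Xtr_s)
            query_coords = project(model, Xq_s)
        else:
            train_coords, query_coords = Xtr_s, Xq_s
        row_preds = knn_classify(train_coords, ytr, query_coords, k=config.k)
        diff = query_coords[:, None, :] - train_coords[None, :, :]
        nearest = np.sqrt(np.sum(diff * diff, axis=2)).min(axis=1)
        truths.append(group_truth[g])
        preds.append(_majority_vote(row_preds, list(nearest)))
    return build_report(truths, preds, config_echo=config.echo())


def build_report(
    truths: Sequence[str],
    preds: Sequence[str],
    config_echo: Optional[dict] = None,
) -> ClassificationReport:
    truths = list(map(str, truths))
    preds = list(map(str, preds))
    classes = sorted(set(truths) | set(preds))
    # canonical study ordering when applicable
    canonical = [g.value for g in GroupLabel]
    if set(classes) <= set(canonical):
        classes = [c for c in canonical if c in classes]
    index = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(truths, preds):
        confusion[index[t], index[p]] += 1
    row_sums = confusion.sum(axis=1)
    per_class = {
        c: (confusion[i, i] / row_sums[i]) if row_sums[i] else float("nan")
        for i, c in enumerate(classes)
    }
    overall = float(np.trace(confusion) / confusion.sum())
    binary = (
        collapse_binary(truths, preds) if BINARY_POSITIVE in classes else None
    )
    return ClassificationReport(
        classes=classes,
        confusion=confusion,
        per_class_accuracy=per_class,
        overall_accuracy=overall,
        binary_accuracy=binary,
        config_echo=config_echo or {},
    )


def collapse_binary(
    truths: Sequence[str],
    preds: Sequence[str],
    positive: str = BINARY_POSITIVE,
) -> float:
    """Accuracy after relabeling everything except ``positive`` as one class."""
    t = np.array([str(x) == positive for x in truths])
    p = np.array([str(x) == positive for x in preds])
    if t.size == 0:
        raise ValueError("no predictions to collapse")
    return float(np.mean(t == p))


def chance_null(labels: Sequence) -> ChanceNull:
    """Analytic null under prior-proportional random assignment."""
    y = _as_label_array(labels)
    n = len(y)
    if n == 0:
        raise ValueError("empty labels")
    props = {c: float(np.mean(y == c)) for c in sorted(set(y))}
    mean = sum(p * p for p in props.values())
    sd = math.sqrt(mean * (1.0 - mean) / n)
    return ChanceNull(mean=mean, sd=sd, n=n, class_proportions=props)


def permutation_null(
    labels: Sequence,
    n_reps: int = 200,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, float]:
    """Monte-Carlo null: accuracy of a random relabeling, mean and SE.

    Cross-checks the analytic :func:`chance_null` (agrees within ~2 SE).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    y = _as_label_array(labels)
    if len(y) == 0:
        raise ValueError("empty labels")
    rng = rng or np.random.default_rng()
    accs = np.empty(n_reps)
    for r in range(n_reps):
        perm = rng.permutation(len(y))
        accs[r] = np.mean(y[perm] == y)
    return float(accs.mean()), float(accs.std(ddof=1) / math.sqrt(n_reps))
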