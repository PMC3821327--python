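"""E-nose feature extraction and classification.

The single feature per sensor is the maximum change in resistance relative to
the pre-injection baseline; exploratory PCA and the shared LDA+KNN
leave-one-out machinery operate on the resulting 18-vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .discriminant import ClassificationReport, LoocvConfig, loocv
from .io_formats import EnoseRecord, GroupLabel, N_SENSORS

__all__ = [
    "EnoseFeatureVector",
    "PcaResult",
    "max_delta_r",
    "pca",
    "enose_classify",
]


@dataclass
class EnoseFeatureVector:
    """Per-sensor maximum resistance change for one injection."""

    values: np.ndarray
    sample_id: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.shape != (N_SENSORS,):
            raise ValueError(f"feature vector must have {N_SENSORS} entries")


def max_delta_r(record: EnoseRecord, mode: str = "absolute") -> EnoseFeatureVector:
    """Maximum |R(t) - baseline| per sensor.

    mode="absolute" (default) returns ohms; mode="relative" divides by the
    baseline; mode="signed" keeps the sign of the largest excursion.
    """
    delta = record.resistances - record.baseline[:, None]
    if mode == "signed":
        idx = np.argmax(np.abs(delta), axis=1)
        values = delta[np.arange(delta.shape[0]), idx]
    elif mode in ("absolute", "relative"):
        values = np.max(np.abs(delta), axis=1)
        if mode == "relative":
            if np.any(record.baseline <= 0):
                raise ValueError("relative mode requires positive baselines")
            values = values / record.baseline
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return EnoseFeatureVector(
        values=values, sample_id=record.sample_id, replicate=record.replicate
    )


@dataclass
class PcaResult:
    scores: np.ndarray  # (samples, components)
    loadings: np.ndarray  # (variables, components), orthonormal columns
    explained_variance_fraction: np.ndarray
    mean: np.ndarray


def pca(features: np.ndarray, scale: bool = False) -> PcaResult:
    """Principal components of column-mean-centered data (SVD based).

    No variance scaling by default; pass ``scale=True`` for unit-variance
    columns.  Components are ordered by explained variance; signs follow a
    fixed convention (largest-magnitude loading positive).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("PCA requires a 2-D matrix with >= 2 samples")
    mean = X.mean(axis=0)
    Xc = X - mean
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention for determinism
    for j in range(Vt.shape[0]):
        pivot = np.argmax(np.abs(Vt[j]))
        if Vt[j, pivot] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]
    var = s**2
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    return PcaResult(
        scores=U * s,
        loadings=Vt.T,
        explained_variance_fraction=frac,
        mean=mean,
    )


def enose_classify(
    records_by_sample: dict[str, Sequence[EnoseRecord]],
    labels: dict[str, GroupLabel | str],
    mode: str = "absolute",
    k: int = 3,
    grouped: bool = True,
    config: Optional[LoocvConfig] = None,
) -> ClassificationReport:
    """Replicate-grouped leave-one-out classification of e-nose samples.

    Features are max_delta_r per injection; all replicates of a biological
    sample are held out together (unless ``grouped=False``) and vote by
    majority.
    """
    rows: list[np.ndarray] = []
    row_labels: list[str] = []
    row_groups: list[str] = []
    for sid in sorted(records_by_sample):
        if sid not in labels:
            raise ValueError(f"no label for sample {sid!r}")
        for rec in records_by_sample[sid]:
            rows.append(max_delta_r(rec, mode=mode).values)
            row_labels.append(str(labels[sid]))
            row_groups.append(sid if grouped else f"{sid}#{rec.replicate}")
    if not rows:
        raise ValueError("no records supplied")
    X = np.vstack(rows)
    cfg = config or LoocvConfig(k=k)
    cfg.groups = row_groups
    report = loocv(X, row_labels, cfg)
    report.config_echo.update({"feature": "max_delta_r", "mode": mode})
    return report
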