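"""FAIMS dispersion-matrix feature pipeline.

A scan's two polarity matrices are concatenated into one long vector, wavelet
transformed with an orthonormal Daubechies-4 filter (periodic boundaries),
and scored variable-by-variable with two scatter statistics:

* ``within``  — the class scatter ``(sum_i sigma_i)^2``, where ``sigma_i`` is
  the sample standard deviation of the variable inside class ``i``;
* ``between`` — ``sigma_mu^2 / within``, where ``sigma_mu`` is the standard
  deviation of the per-class means.

Variables are selected by thresholding both statistics, and a 2-D grid of
thresholds is explored with full leave-one-out LDA+KNN reclassification per
cell.  Cells whose accuracy exceeds the chance null by more than three
standard deviations form the robust region.

Threshold direction note: taken literally, "below the threshold" for the
between statistic would favour the *least* discriminative variables (large
``between`` means well-separated class means).  The default therefore selects
``within < t_w`` AND ``between > t_b``; both directions are configurable via
``within_op`` / ``between_op``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .discriminant import (
    ChanceNull,
    chance_null,
    fit_lda,
    knn_classify,
    project,
)
from .io_formats import N_CV_STEPS, N_DF_LINES, FaimsScan

__all__ = [
    "FEATURE_LENGTH",
    "FeatureVector",
    "WaveletFeatures",
    "ScatterStats",
    "GridConfig",
    "ThresholdGridResult",
    "RobustRegion",
    "concatenate_polarities",
    "wavelet_transform",
    "inverse_wavelet",
    "compute_scatter_stats",
    "select_variables",
    "build_feature_matrix",
    "explore_threshold_grid",
    "find_robust_region",
]

#: concatenated feature length: 2 polarities x 51 DF lines x 512 CV steps
FEATURE_LENGTH = 2 * N_DF_LINES * N_CV_STEPS  # 52,224

DEFAULT_WAVELET_DEPTH = 9

_SQRT3 = math.sqrt(3.0)
# Daubechies-4 low-pass filter (two vanishing moments, length 4), orthonormal
_D4_H = np.array(
    [1.0 + _SQRT3, 3.0 + _SQRT3, 3.0 - _SQRT3, 1.0 - _SQRT3]
) / (4.0 * math.sqrt(2.0))
# quadrature mirror high-pass: g[k] = (-1)^k h[3-k]
_D4_G = np.array([_D4_H[3], -_D4_H[2], _D4_H[1], -_D4_H[0]])


@dataclass
class FeatureVector:
    """Concatenated raw scan: positive polarity first, row-major by DF line."""

    values: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()


@dataclass
class WaveletFeatures:
    """Multilevel D4 coefficients, laid out [cA_L | cD_L | ... | cD_1]."""

    coefficients: np.ndarray
    levels: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float).ravel()


def concatenate_polarities(scan: FaimsScan) -> FeatureVector:
    """Flatten both polarity matrices into one 52,224-element vector.

    Element ``polarity * 26112 + df * 512 + cv`` holds the intensity at
    (polarity, df line, cv step); polarity 0 is positive.
    """
    values = np.concatenate([scan.positive.ravel(), scan.negative.ravel()])
    assert values.size == FEATURE_LENGTH
    return FeatureVector(values=values, sample_id=scan.sample_id)


# ---------------------------------------------------------------------------
# Daubechies-4 wavelet (periodic, orthonormal)
# ---------------------------------------------------------------------------

def _dwt_step(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    m = x.size
    if m % 2:
        raise ValueError(
            f"cannot halve a length-{m} signal; reduce the decomposition depth"
        )
    idx = (np.arange(0, m, 2)[:, None] + np.arange(4)[None, :]) % m
    windows = x[idx]
    return windows @ _D4_H, windows @ _D4_G


def _idwt_step(approx: np.ndarray, detail: np.ndarray) -> np.ndarray:
    m = 2 * approx.size
    idx = (np.arange(0, m, 2)[:, None] + np.arange(4)[None, :]) % m
    x = np.zeros(m)
    contrib = approx[:, None] * _D4_H[None, :] + detail[:, None] * _D4_G[None, :]
    np.add.at(x, idx, contrib)
    return x


def _max_depth(n: int) -> int:
    depth = 0
    while n % 2 == 0 and n > 1:
        n //= 2
        depth += 1
    return depth


def wavelet_transform(
    v: FeatureVector | np.ndarray, levels: Optional[int] = None
) -> WaveletFeatures:
    """Multilevel orthonormal D4 decomposition with periodic boundaries.

    Depth defaults to 9 for the full 52,224-element vector (which halves
    evenly nine times, down to length 102) and to the maximal even-halving
    depth, capped at 9, for other lengths.  The transform preserves length
    and energy and is inverted exactly by :func:`inverse_wavelet`.
    """
    if isinstance(v, FeatureVector):
        x, sid = v.values, v.sample_id
    else:
        x, sid = np.asarray(v, dtype=float).ravel(), ""
    if levels is None:
        levels = min(DEFAULT_WAVELET_DEPTH, _max_depth(x.size))
    if levels < 1:
        raise ValueError("decomposition depth must be >= 1")
    details: list[np.ndarray] = []
    approx = x
    for _ in range(levels):
        approx, d = _dwt_step(approx)
        details.append(d)
    coeffs = np.concatenate([approx] + details[::-1])
    return WaveletFeatures(coefficients=coeffs, levels=levels, sample_id=sid)


def inverse_wavelet(w: WaveletFeatures) -> FeatureVector:
    """Reconstruct the original vector from its D4 coefficients."""
    n = w.coefficients.size
    approx_len = n >> w.levels
    if approx_len << w.levels != n:
        raise ValueError("coefficient length is not divisible by 2**levels")
    approx = w.coefficients[:approx_len]
    pos = approx_len
    for _ in range(w.levels):
        # each detail block has the same length as the approx it merges with
        detail = w.coefficients[pos : pos + approx.size]
        if detail.size != approx.size:
            raise ValueError("coefficient array shorter than declared layout")
        pos += detail.size
        approx = _idwt_step(approx, detail)
    return FeatureVector(values=approx, sample_id=w.sample_id)


# ---------------------------------------------------------------------------
# Scatter statistics and variable selection
# ---------------------------------------------------------------------------

@dataclass
class ScatterStats:
    """Per-variable class scatter and between-class scatter ratio.

    Degenerate conventions: a variable constant everywhere gets
    ``between = 0`` (never selected); one constant within each class but with
    distinct class means gets ``between = +inf`` (passes any finite
    threshold).
    """

    within: np.ndarray
    between: np.ndarray

    def __post_init__(self) -> None:
        self.within = np.asarray(self.within, dtype=float).ravel()
        self.between = np.asarray(self.between, dtype=float).ravel()
        if self.within.shape != self.between.shape:
            raise ValueError("within/between must have equal lengths")


def compute_scatter_stats(
    features: np.ndarray, labels: Sequence
) -> ScatterStats:
    """Compute ``within = (sum_i sigma_i)^2`` and ``between = sigma_mu^2 / within``.

    Standard deviations use the n-1 denominator.  Requires >= 2 classes with
    >= 2 samples each.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be 2-D (samples x variables)")
    y = np.array([str(lab) for lab in labels], dtype=object)
    if len(y) != X.shape[0]:
        raise ValueError("labels length must match feature rows")
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("scatter statistics require >= 2 classes")
    sigma_sum = np.zeros(X.shape[1])
    class_means = np.empty((len(classes), X.shape[1]))
    for i, c in enumerate(classes):
        Xc = X[y == c]
        if Xc.shape[0] < 2:
            raise ValueError(
                f"class {c!r} has fewer than 2 samples; sigma is undefined"
            )
        sigma_sum += Xc.std(axis=0, ddof=1)
        class_means[i] = Xc.mean(axis=0)
    within = sigma_sum**2
    sigma_mu_sq = class_means.var(axis=0, ddof=1)
    between = np.zeros(X.shape[1])
    nonzero = within > 0
    between[nonzero] = sigma_mu_sq[nonzero] / within[nonzero]
    degenerate = (~nonzero) & (sigma_mu_sq > 0)
    between[degenerate] = np.inf
    return ScatterStats(within=within, between=between)


_OPS = {
    "lt": np.less,
    "gt": np.greater,
}


def select_variables(
    stats: ScatterStats,
    within_threshold: float,
    between_threshold: float,
    within_op: str = "lt",
    between_op: str = "gt",
) -> np.ndarray:
    """Indices passing both threshold comparisons (strict inequalities)."""
    if within_op not in _OPS or between_op not in _OPS:
        raise ValueError("comparison directions must be 'lt' or 'gt'")
    mask = _OPS[within_op](stats.within, within_threshold) & _OPS[between_op](
        stats.between, between_threshold
    )
    return np.nonzero(mask)[0]


def build_feature_matrix(
    scans: Sequence[FaimsScan], levels: Optional[int] = DEFAULT_WAVELET_DEPTH
) -> np.ndarray:
    """Stack wavelet_transform(concatenate_polarities(scan)) row per sample."""
    rows = [
        wavelet_transform(concatenate_polarities(s), levels=levels).coefficients
        for s in scans
    ]
    return np.vstack(rows)


# ---------------------------------------------------------------------------
# Threshold-grid exploration
# ---------------------------------------------------------------------------

@dataclass
class GridConfig:
    """Shape and evaluation settings of the 2-D threshold search.

    Within thresholds default to linear empirical quantiles
    {2.5%, 7.5%, ...} of the full-data within-scatter distribution.  Between
    thresholds default to geometrically spaced *upper-tail* quantiles, from
    the median down to a tail of one variable: with tens of thousands of
    variables and a selection cap near the sample count, only the extreme
    upper tail of the between statistic yields evaluable cells, so a linear
    quantile grid would leave every cell undefined.  Explicit threshold
    arrays override either placement.
    """

    n_within: int = 20
    n_between: int = 20
    within_thresholds: Optional[np.ndarray] = None
    between_thresholds: Optional[np.ndarray] = None
    k: int = 3
    regularization: float = 1e-6
    cap: Optional[int] = None  # default: min(n_samples - n_classes, 500)
    within_op: str = "lt"
    between_op: str = "gt"
    groups: Optional[Sequence] = None

    def echo(self) -> dict:
        return {
            "n_within": self.n_within,
            "n_between": self.n_between,
            "k": self.k,
            "regularization": self.regularization,
            "cap": self.cap,
            "within_op": self.within_op,
            "between_op": self.between_op,
        }


@dataclass
class ThresholdGridResult:
    within_thresholds: np.ndarray
    between_thresholds: np.ndarray
    accuracy: np.ndarray  # (n_within, n_between); NaN marks undefined cells
    n_selected: np.ndarray  # selected-variable count on the full data
    robust_mask: np.ndarray  # accuracy > null.mean + 3 * null.sd
    null: ChanceNull
    stats: ScatterStats  # full-data scatter statistics
    config: GridConfig
    undefined_reasons: dict[tuple[int, int], str] = field(default_factory=dict)


@dataclass
class RobustRegion:
    found: bool
    mask: np.ndarray
    chosen_cell: Optional[tuple[int, int]]
    chosen_thresholds: Optional[tuple[float, float]]
    chosen_variables: Optional[np.ndarray]


def _quantile_grid(values: np.ndarray, n: int) -> np.ndarray:
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise ValueError("no finite statistic values to place a grid on")
    qs = np.linspace(0.025, 0.975, n)
    return np.quantile(finite, qs)


def _tail_quantile_grid(values: np.ndarray, n: int) -> np.ndarray:
    """Thresholds at upper-tail fractions geomspaced from 1/2 to 1/n_vars."""
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise ValueError("no finite statistic values to place a grid on")
    tails = np.geomspace(0.5, 1.0 / finite.size, n)
    return np.quantile(finite, 1.0 - tails)


def explore_threshold_grid(
    features: np.ndarray,
    labels: Sequence,
    grid_config: Optional[GridConfig] = None,
) -> ThresholdGridResult:
    """LOOCV accuracy over a grid of (within, between) thresholds.

    For each held-out sample the scatter statistics are recomputed on the
    training fold once and shared across all grid cells; each cell then
    selects its variables, refits LDA, and KNN-classifies the held-out
    sample.  Cells that select zero variables, or more than the cap, on any
    fold (or on the full data) are marked undefined (NaN accuracy).
    """
    cfg = grid_config or GridConfig()
    X = np.asarray(features, dtype=float)
    y = np.array([str(lab) for lab in labels], dtype=object)
    n = X.shape[0]
    classes = sorted(set(y))
    full_stats = compute_scatter_stats(X, y)
    wt = (
        np.asarray(cfg.within_thresholds, dtype=float)
        if cfg.within_thresholds is not None
        else _quantile_grid(full_stats.within, cfg.n_within)
    )
    bt = (
        np.asarray(cfg.between_thresholds, dtype=float)
        if cfg.between_thresholds is not None
        else _tail_quantile_grid(full_stats.between, cfg.n_between)
    )
    cap = cfg.cap if cfg.cap is not None else min(n - len(classes), 500)

    groups = (
        np.array([str(g) for g in cfg.groups], dtype=object)
        if cfg.groups is not None
        else np.array([f"row{i}" for i in range(n)], dtype=object)
    )
    group_order: list[str] = []
    group_rows: dict[str, list[int]] = {}
    for i, g in enumerate(groups):
        if g not in group_rows:
            group_rows[g] = []
            group_order.append(g)
        group_rows[g].append(i)

    shape = (wt.size, bt.size)
    correct = np.zeros(shape)
    total = np.zeros(shape)
    defined = np.ones(shape, dtype=bool)
    reasons: dict[tuple[int, int], str] = {}
    n_selected = np.zeros(shape, dtype=int)
    for iw, w_thr in enumerate(wt):
        for ib, b_thr in enumerate(bt):
            idx = select_variables(
                full_stats, w_thr, b_thr, cfg.within_op, cfg.between_op
            )
            n_selected[iw, ib] = idx.size
            if idx.size == 0:
                defined[iw, ib] = False
                reasons[(iw, ib)] = "no variables selected on the full data"
            elif idx.size > cap:
                defined[iw, ib] = False
                reasons[(iw, ib)] = (
                    f"{idx.size} variables selected exceeds cap {cap}"
                )

    for g in group_order:
        held = np.asarray(group_rows[g])
        mask = np.ones(n, dtype=bool)
        mask[held] = False
        Xtr, ytr = X[mask], y[mask]
        fold_stats = compute_scatter_stats(Xtr, ytr)
        truth = y[held[0]]
        lda_cache: dict[bytes, tuple] = {}
        for iw, w_thr in enumerate(wt):
            for ib, b_thr in enumerate(bt):
                if not defined[iw, ib]:
                    continue
                idx = select_variables(
                    fold_stats, w_thr, b_thr, cfg.within_op, cfg.between_op
                )
                if idx.size == 0 or idx.size > cap:
                    defined[iw, ib] = False
                    reasons[(iw, ib)] = (
                        f"fold {g!r} selected {idx.size} variables "
                        f"(cap {cap})"
                    )
                    continue
                key = idx.tobytes()
                if key not in lda_cache:
                    try:
                        model = fit_lda(
                            Xtr[:, idx], ytr, regularization=cfg.regularization
                        )
                    except ValueError as exc:
                        defined[iw, ib] = False
                        reasons[(iw, ib)] = f"LDA failed on fold {g!r}: {exc}"
                        continue
                    lda_cache[key] = (model, project(model, Xtr[:, idx]))
                model, train_coords = lda_cache[key]
                query_coords = project(model, X[held][:, idx])
                row_preds = knn_classify(
                    train_coords, ytr, query_coords, k=cfg.k
                )
                # majority vote over replicate rows of the held-out sample
                votes: dict[str, int] = {}
                for p in row_preds:
                    votes[p] = votes.get(p, 0) + 1
                best = max(votes.values())
                pred = sorted(c for c, v in votes.items() if v == best)[0]
                correct[iw, ib] += pred == truth
                total[iw, ib] += 1

    accuracy = np.full(shape, np.nan)
    ok = defined & (total > 0)
    accuracy[ok] = correct[ok] / total[ok]
    null = chance_null([y[group_rows[g][0]] for g in group_order])
    robust = np.zeros(shape, dtype=bool)
    robust[ok] = accuracy[ok] > null.threshold
    return ThresholdGridResult(
        within_thresholds=wt,
        between_thresholds=bt,
        accuracy=accuracy,
        n_selected=n_selected,
        robust_mask=robust,
        null=null,
        stats=full_stats,
        config=cfg,
        undefined_reasons=reasons,
    )


def default_selection_thresholds(
    stats: ScatterStats, cap: int, target: Optional[int] = None
) -> tuple[float, float]:
    """A fixed threshold pair selecting ~``target`` variables on these stats.

    Within threshold at the median of the within statistic; between
    threshold placed so that exactly ``target`` (default cap // 2, at least
    1) variables pass both comparisons on the supplied statistics.
    """
    if target is None:
        target = max(1, cap // 2)
    wt = float(np.median(stats.within[np.isfinite(stats.within)]))
    candidates = stats.between[stats.within < wt]
    if candidates.size == 0:
        raise ValueError("no variables below the median within threshold")
    target = min(target, candidates.size)
    ranked = np.sort(candidates)[::-1]
    hi = ranked[target - 1]
    lo = ranked[target] if target < ranked.size else hi - max(abs(hi), 1.0)
    bt = float((hi + lo) / 2.0) if np.isfinite(hi) else float(ranked[target])
    return wt, bt


def faims_classify(
    features: np.ndarray,
    labels: Sequence,
    k: int = 3,
    cap: Optional[int] = None,
    groups: Optional[Sequence] = None,
):
    """Single-threshold FAIMS LOOCV at fixed, data-scaled thresholds.

    Convenience wrapper (used for calibration runs): picks one threshold
    pair via :func:`default_selection_thresholds` and runs the shared
    leave-one-out loop with per-fold selection refitting.
    """
    from .discriminant import LoocvConfig, loocv

    X = np.asarray(features, dtype=float)
    y = list(labels)
    n_classes = len(set(map(str, y)))
    if cap is None:
        cap = min(X.shape[0] - n_classes, 500)
    stats = compute_scatter_stats(X, y)
    thresholds = default_selection_thresholds(stats, cap)
    return loocv(
        X,
        y,
        LoocvConfig(k=k, selection_thresholds=thresholds, groups=groups),
    )


def find_robust_region(
    result: ThresholdGridResult, null: Optional[ChanceNull] = None
) -> RobustRegion:
    """Locate grid cells beating chance by > 3 SD and pick the best one.

    Ties on accuracy prefer more selected variables, then the smallest
    within threshold.  Returns ``found=False`` (not an exception) when no
    cell is robust.
    """
    null = null or result.null
    acc = result.accuracy
    ok = np.isfinite(acc)
    mask = np.zeros_like(ok)
    mask[ok] = acc[ok] > null.threshold
    if not mask.any():
        return RobustRegion(
            found=False,
            mask=mask,
            chosen_cell=None,
            chosen_thresholds=None,
            chosen_variables=None,
        )
    cells = np.argwhere(mask)
    best = min(
        (tuple(c) for c in cells),
        key=lambda c: (
            -acc[c],
            -result.n_selected[c],
            result.within_thresholds[c[0]],
        ),
    )
    wt = float(result.within_thresholds[best[0]])
    bt = float(result.between_thresholds[best[1]])
    chosen_vars = select_variables(
        result.stats, wt, bt, result.config.within_op, result.config.between_op
    )
    return RobustRegion(
        found=True,
        mask=mask,
        chosen_cell=(int(best[0]), int(best[1])),
        chosen_thresholds=(wt, bt),
        chosen_variables=chosen_vars,
    )
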