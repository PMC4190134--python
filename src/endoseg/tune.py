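"""Supervised learning of segmentation control parameters.

Given a database of gray images with expert reference contours, the quality
of a parameter set p for algorithm A under criterion C is

    Q_C(A_p, I) = C(A_p(I), R(I))

with C either ε at a fixed tolerance ρ or the figure of merit (both are
dissimilarities, lower is better).  The best parameter set is the grid
point minimising an aggregate of Q over the images: the mean, the trimmed
mean that discards the fraction k of worst (largest) values — robust to a
few poor-quality images — or the median.  At k = 0 the trimmed-mean
optimum coincides with the plain mean optimum.

Generalisation is assessed by K-fold cross-validation: learn the parameters
on K−1 folds, score them on the held-out fold (Q_i^CV), and compare with
the best score the test fold itself could achieve (Q̃_i^CV ≤ Q_i^CV).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import evaluate, segmenters


@dataclass(frozen=True)
class Criterion:
    """Comparison criterion id: ``epsilon`` at a tolerance ``rho``, or ``fom``."""

    name: str = "epsilon"
    rho: float = 2.0

    def __post_init__(self) -> None:
        if self.name not in ("epsilon", "fom"):
            raise ValueError("criterion must be 'epsilon' or 'fom'")
        if self.rho < 0:
            raise ValueError("rho must be >= 0")

    def __call__(self, X: np.ndarray, R: np.ndarray) -> float:
        if self.name == "epsilon":
            return evaluate.epsilon(R, X, self.rho)
        return evaluate.fom(R, X)


#: worst finite score charged when a segmenter fails on an image
FAILURE_PENALTY = {"fom": 1.0, "epsilon": 2.0}


def quality(
    method: str,
    p,
    img: np.ndarray,
    ref: np.ndarray,
    criterion: Criterion,
) -> float:
    """Q_C(A_p, I): run the segmenter and compare its contours to ``ref``.

    A segmentation failure (degenerate pipeline stage) maps to the worst
    finite score for the criterion rather than propagating, so a grid
    search can traverse bad parameter regions.
    """
    if not np.asarray(ref).astype(bool).any():
        raise ValueError("reference contour map must be nonempty")
    try:
        seg = segmenters.segment(img, method, p)
    except segmenters.SegmentationError:
        return FAILURE_PENALTY[criterion.name]
    return criterion(seg.contours, ref)


@dataclass
class ParameterGrid:
    """Cartesian grid of candidate parameter values for one method."""

    method: str
    axes: dict[str, list]

    def __post_init__(self) -> None:
        if self.method not in segmenters.METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        cls = segmenters.METHODS[self.method][1]
        valid = set(cls.__dataclass_fields__)
        for name, vals in self.axes.items():
            if name not in valid:
                raise ValueError(f"{name!r} is not a parameter of {self.method!r}")
            if len(vals) == 0:
                raise ValueError(f"axis {name!r} is empty")

    def points(self) -> list:
        """All parameter sets on the grid, in lexicographic axis order."""
        cls = segmenters.METHODS[self.method][1]
        names = [n for n in cls.__dataclass_fields__ if n in self.axes]
        combos = [{}]
        for n in names:
            combos = [dict(c, **{n: v}) for c in combos for v in self.axes[n]]
        return [cls(**c) for c in combos]


@dataclass
class QualityTable:
    """Matrix of Q values indexed by (image, parameter set)."""

    images: list[str]
    params: list
    values: np.ndarray  # shape (n_images, n_params)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.images), len(self.params)):
            raise ValueError("table dimensions do not match index lists")
        if not np.isfinite(self.values).all():
            raise ValueError("quality values must be finite")

    def subset(self, image_idx) -> "QualityTable":
        idx = list(image_idx)
        return QualityTable(
            images=[self.images[i] for i in idx],
            params=self.params,
            values=self.values[idx, :],
        )


def compute_quality_table(
    images: dict[str, np.ndarray],
    refs: dict[str, np.ndarray],
    grid: ParameterGrid,
    criterion: Criterion,
) -> QualityTable:
    """Evaluate every grid point on every image of the database."""
    ids = list(images)
    params = grid.points()
    values = np.empty((len(ids), len(params)))
    for i, img_id in enumerate(ids):
        for j, p in enumerate(params):
            values[i, j] = quality(grid.method, p, images[img_id], refs[img_id], criterion)
    return QualityTable(images=ids, params=params, values=values)


def trimmed_mean(values: np.ndarray, k: float) -> float:
    """Mean after discarding the floor(k·N) largest values (the high end)."""
    if not 0.0 <= k <= 0.5:
        raise ValueError("k must lie in [0, 0.5]")
    v = np.sort(np.asarray(values, dtype=float))
    n_drop = int(np.floor(k * len(v)))
    kept = v[: len(v) - n_drop] if n_drop else v
    return float(np.mean(kept))


@dataclass(frozen=True)
class TuningResult:
    """Optima under the three aggregators of the per-image quality."""

    p_hat: object  # argmin of the mean
    Q_hat: float
    p_hat_k: object  # argmin of the trimmed mean at k
    Q_hat_k: float
    p_tilde: object  # argmin of the median
    Q_tilde: float
    k: float


def _argmin_with_ties(agg: np.ndarray, params: list) -> int:
    """Index of the minimal aggregate; ties go to the lexicographically
    smallest parameter tuple for determinism."""
    best = np.nonzero(agg == agg.min())[0]
    if len(best) == 1:
        return int(best[0])
    return int(min(best, key=lambda j: params[j].astuple()))


def grid_search(table: QualityTable, k: float = 0.5) -> TuningResult:
    """Best parameter set under the mean, trimmed mean at k, and median."""
    if len(table.images) == 0 or len(table.params) == 0:
        raise ValueError("empty quality table")
    means = table.values.mean(axis=0)
    tmeans = np.array([trimmed_mean(table.values[:, j], k) for j in range(len(table.params))])
    medians = np.median(table.values, axis=0)
    j_mean = _argmin_with_ties(means, table.params)
    j_trim = _argmin_with_ties(tmeans, table.params)
    j_med = _argmin_with_ties(medians, table.params)
    return TuningResult(
        p_hat=table.params[j_mean],
        Q_hat=float(means[j_mean]),
        p_hat_k=table.params[j_trim],
        Q_hat_k=float(tmeans[j_trim]),
        p_tilde=table.params[j_med],
        Q_tilde=float(medians[j_med]),
        k=k,
    )


def projection(
    table: QualityTable, anchor, param_name: str, k: float = 0.5
) -> list[tuple[float, float]]:
    """Quality profile of one parameter with all others fixed at the anchor.

    Returns (value, trimmed-mean quality) pairs as ``param_name`` sweeps
    the values present on the grid while every other field equals the
    anchor's.
    """
    if param_name not in type(anchor).__dataclass_fields__:
        raise ValueError(f"unknown parameter axis {param_name!r}")
    rows = []
    for j, p in enumerate(table.params):
        others_match = all(
            getattr(p, f) == getattr(anchor, f)
            for f in type(anchor).__dataclass_fields__
            if f != param_name
        )
        if others_match:
            rows.append(
                (getattr(p, param_name), trimmed_mean(table.values[:, j], k))
            )
    if not rows:
        raise ValueError("anchor does not lie on the grid")
    return sorted(rows)


@dataclass(frozen=True)
class FoldResult:
    test_images: list[str]
    p_learned: object
    Q_cv: float  # learned-on-train parameters scored on the test fold
    Q_tilde_cv: float  # best achievable mean on the test fold


@dataclass(frozen=True)
class CVReport:
    folds: list[FoldResult]
    Q_cv: float
    Q_tilde_cv: float

    def to_dict(self) -> dict:
        return {
            "folds": [
                {
                    "test_images": f.test_images,
                    "learned_parameters": list(f.p_learned.astuple()),
                    "Q_i_CV": f.Q_cv,
                    "Q_tilde_i_CV": f.Q_tilde_cv,
                }
                for f in self.folds
            ],
            "Q_CV": self.Q_cv,
            "Q_tilde_CV": self.Q_tilde_cv,
        }


def kfold_split(n: int, K: int, seed: int) -> list[np.ndarray]:
    """Seeded shuffle of range(n) into K near-equal folds."""
    if K < 2:
        raise ValueError("K must be >= 2")
    if K > n:
        raise ValueError("more folds than images")
    order = np.random.default_rng(seed).permutation(n)
    return [np.sort(f) for f in np.array_split(order, K)]


def kfold_cv_from_table(table: QualityTable, K: int, seed: int) -> CVReport:
    """K-fold cross-validation on a precomputed quality table.

    Per fold: the mean-aggregator grid search on the training images gives
    the learned parameters; Q_i^CV is their mean quality on the test fold,
    and Q̃_i^CV the test fold's own best achievable mean.
    """
    n = len(table.images)
    folds_idx = kfold_split(n, K, seed)
    folds = []
    for test_idx in folds_idx:
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        train = table.subset(train_idx)
        test = table.subset(test_idx)
        learned = grid_search(train, k=0.0)
        j_learned = table.params.index(learned.p_hat)
        q_cv = float(test.values[:, j_learned].mean())
        q_tilde_cv = float(test.values.mean(axis=0).min())
        folds.append(
            FoldResult(
                test_images=list(test.images),
                p_learned=learned.p_hat,
                Q_cv=q_cv,
                Q_tilde_cv=q_tilde_cv,
            )
        )
    return CVReport(
        folds=folds,
        Q_cv=float(np.mean([f.Q_cv for f in folds])),
        Q_tilde_cv=float(np.mean([f.Q_tilde_cv for f in folds])),
    )


def kfold_cv(
    images: dict[str, np.ndarray],
    refs: dict[str, np.ndarray],
    grid: ParameterGrid,
    criterion: Criterion,
    K: int,
    seed: int,
) -> CVReport:
    """End-to-end K-fold cross-validation from a raw image database."""
    table = compute_quality_table(images, refs, grid, criterion)
    return kfold_cv_from_table(table, K, seed)
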