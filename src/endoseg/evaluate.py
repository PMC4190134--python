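"""Supervised dissimilarity criteria between contour segmentations.

Two contour-based criteria that tolerate small spatial variations between a
reference contour set R (typically an expert drawing) and a candidate X:

* the ε dissimilarity criterion — a normalised symmetric difference in
  which each set is first dilated by a Euclidean disk of radius ρ (the
  spatial tolerance), so that contour displacements within ρ pixels do not
  count as errors:

      ε_ρ(R, X) = #{ (X ∖ R⊕ρN) ∪ (R ∖ X⊕ρN) } / #{ R⊕ρN }

  ε is 0 iff the two sets agree within the tolerance tube; it is *not* a
  metric (symmetry and the triangle inequality both fail), which matches
  how human observers compare drawings.

* the figure of merit — a distance-weighted contour agreement measure,
  oriented here as a dissimilarity (0 = perfect) so that parameter tuning
  can minimise both criteria uniformly:

      fom(R, X) = 1 − (1 / max{#R, #X}) · Σ_{p∈X} 1 / (1 + d²(p, R))

The tolerance ρ itself is calibrated from repeated expert drawings of the
same image: the mean ε over all ordered pairs of drawings is computed as a
function of ρ, and the smallest ρ bringing it under a chosen error level is
retained (``select_tolerance``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class ToleranceCurve:
    """Mean pairwise ε between expert drawings as a function of ρ."""

    rho_values: np.ndarray
    mean_epsilon: np.ndarray


def _as_bool(img: np.ndarray) -> np.ndarray:
    return np.asarray(img).astype(bool)


def symmetric_difference(R: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Pixels belonging to exactly one of the two sets: (R∪X) ∖ (R∩X)."""
    R, X = _as_bool(R), _as_bool(X)
    if R.shape != X.shape:
        raise ValueError(f"shape mismatch: {R.shape} vs {X.shape}")
    return R ^ X

def minkowski_dilate(X: np.ndarray, rho: float) -> np.ndarray:
    """X ⊕ ρN: all pixels within Euclidean distance ρ of the set X.

    Realised by thresholding the exact Euclidean distance transform, so ρ
    need not be an integer; ρ = 0 is the identity.
    """
    X = _as_bool(X)
    if rho < 0:
        raise ValueError("rho must be >= 0")
    if rho == 0 or not X.any():
        return X.copy()
    return ndimage.distance_transform_edt(~X) <= rho


def epsilon(R: np.ndarray, X: np.ndarray, rho: float) -> float:
    """ε dissimilarity with spatial tolerance ρ (0 = agreement within ρ).

    An empty candidate X is a total miss and yields #R / #(R⊕ρN); the
    reference R must be nonempty.
    """
    R, X = _as_bool(R), _as_bool(X)
    if R.shape != X.shape:
        raise ValueError(f"shape mismatch: {R.shape} vs {X.shape}")
    if not R.any():
        raise ValueError("reference contour map must be nonempty")
    R_dil = minkowski_dilate(R, rho)
    X_dil = minkowski_dilate(X, rho)
    mismatch = (X & ~R_dil) | (R & ~X_dil)
    return float(np.count_nonzero(mismatch)) / float(np.count_nonzero(R_dil))


def fom(R: np.ndarray, X: np.ndarray) -> float:
    """Figure of merit, as a dissimilarity in [0, 1] (0 = perfect).

    Each candidate pixel contributes 1/(1 + d²) where d is its Euclidean
    distance to the nearest reference pixel; an empty X scores 1.
    """
    R, X = _as_bool(R), _as_bool(X)
    if R.shape != X.shape:
        raise ValueError(f"shape mismatch: {R.shape} vs {X.shape}")
    n_R = int(np.count_nonzero(R))
    n_X = int(np.count_nonzero(X))
    if n_R == 0:
        raise ValueError("reference contour map must be nonempty")
    if n_X == 0:
        return 1.0
    d = ndimage.distance_transform_edt(~R)
    s = np.sum(1.0 / (1.0 + d[X] ** 2))
    return float(1.0 - s / max(n_R, n_X))


def select_tolerance(
    expert_maps: list[np.ndarray],
    epsilon_max: float,
    rho_max: int = 10,
) -> tuple[int, ToleranceCurve]:
    """Calibrate the tolerance ρ from repeated expert drawings.

    Computes the mean ε over all ordered pairs (i ≠ j) of drawings for each
    integer ρ in [0, rho_max] and returns the smallest ρ whose mean falls
    at or below ``epsilon_max``, together with the full curve.

    Raises
    ------
    ValueError
        Fewer than two drawings, an empty drawing, mismatched shapes, or no
        ρ in range meeting the bound (the curve is attached to the error).
    """
    if len(expert_maps) < 2:
        raise ValueError("need at least two expert drawings")
    maps = [_as_bool(m) for m in expert_maps]
    shape = maps[0].shape
    for m in maps:
        if m.shape != shape:
            raise ValueError("expert drawings must share one shape")
        if not m.any():
            raise ValueError("expert drawings must be nonempty")
    rhos = np.arange(0, int(rho_max) + 1)
    means = np.empty(len(rhos), dtype=float)
    for idx, rho in enumerate(rhos):
        vals = [
            epsilon(maps[i], maps[j], float(rho))
            for i in range(len(maps))
            for j in range(len(maps))
            if i != j
        ]
        means[idx] = float(np.mean(vals))
    curve = ToleranceCurve(rho_values=rhos, mean_epsilon=means)
    ok = np.nonzero(means <= epsilon_max)[0]
    if len(ok) == 0:
        err = ValueError(
            f"no rho in [0, {rho_max}] achieves mean epsilon <= {epsilon_max}"
        )
        err.curve = curve  # attach for diagnosis
        raise err
    return int(rhos[ok[0]]), curve
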