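"""The three marker-controlled watershed segmenters for endothelium images.

All three algorithms share one structure: filter the gray image, extract one
marker per cell, then flood a relief from the markers with a constrained
watershed so every cell receives a closed contour.  They differ in how the
markers and the relief are built:

* Vincent–Masters: cell interiors are local intensity maxima (borders are
  darker), recovered by an h-maxima transform after an alternate sequential
  filter.  Two parameters, ``o`` (filter order) and ``h`` (maxima
  prominence).
* Angulo–Matou: a first border estimate is obtained by opening + Gaussian
  smoothing + black top-hat + threshold; markers are h-maxima of the
  distance map to that estimate.  Five parameters ``s1, g, s2, t, h``; the
  top-hat and h-maxima stages can be bypassed (``s2 = 0`` / ``h = 0``), in
  which case the threshold applies to the smoothed complement and the
  markers are the raw distance-map maxima.
* Gavet–Pinoli: borders are detected as *linear* structures — supremum of
  openings by line segments on the complement of the filtered image,
  automatic threshold, closing, then skeleton pruning that removes every
  non-linear skeleton part; markers come from the opened distance map.
  Four parameters ``c, t_s, o, s``.

Every segmenter is a deterministic function of (image, parameters) and
returns labels that partition the domain together with the 1-px contour
set separating them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from . import morpho


@dataclass(frozen=True)
class ParameterSetVM:
    """Vincent–Masters controls: ASF order ``o``, h-maxima depth ``h``."""

    o: int = 2
    h: float = 10.0

    def __post_init__(self) -> None:
        if self.o < 0 or self.h < 0:
            raise ValueError("parameters must be >= 0")

    def astuple(self) -> tuple:
        return (self.o, self.h)


@dataclass(frozen=True)
class ParameterSetAM:
    """Angulo–Matou controls.

    ``s1``: opening radius, ``g``: Gaussian standard deviation (pixels),
    ``s2``: black top-hat radius (0 bypasses the top-hat), ``t``: border
    threshold (gray levels), ``h``: h-maxima depth on the distance map
    (0 uses the raw distance-map maxima).
    """

    s1: int = 4
    g: float = 4.0
    s2: int = 1
    t: float = 28.0
    h: float = 1.0

    def __post_init__(self) -> None:
        if min(self.s1, self.g, self.s2, self.t, self.h) < 0:
            raise ValueError("parameters must be >= 0")

    def astuple(self) -> tuple:
        return (self.s1, self.g, self.s2, self.t, self.h)


@dataclass(frozen=True)
class ParameterSetGP:
    """Gavet–Pinoli controls.

    ``c``: closing radius after thresholding, ``t_s``: segment length for
    the openings by segments and the skeleton pruning, ``o``: ASF order,
    ``s``: opening radius applied to the distance map before marker
    extraction.  Defaults are the tuned optimum for endothelium images.
    """

    c: int = 2
    t_s: int = 7
    o: int = 4
    s: int = 6

    def __post_init__(self) -> None:
        if min(self.c, self.t_s, self.o, self.s) < 0:
            raise ValueError("parameters must be >= 0")
        if self.t_s < 1:
            raise ValueError("t_s must be >= 1")

    def astuple(self) -> tuple:
        return (self.c, self.t_s, self.o, self.s)


@dataclass(frozen=True)
class Segmentation:
    """Closed-contour segmentation: label partition + 1-px contour set."""

    labels: np.ndarray
    contours: np.ndarray

    @property
    def n_cells(self) -> int:
        return int(self.labels.max())


class SegmentationError(RuntimeError):
    """A pipeline stage produced a degenerate intermediate (no markers,
    empty border estimate, ...); usually a sign of over-filtering."""


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D gray image")
    if img.max() == img.min():
        raise SegmentationError("constant image: nothing to segment")
    return img


def _finish(relief: np.ndarray, markers: np.ndarray) -> Segmentation:
    labels, _ = morpho.watershed_lines(relief, markers)
    return Segmentation(labels=labels, contours=morpho.labels_to_contours(labels))


def segment_vincent_masters(img: np.ndarray, p: ParameterSetVM) -> Segmentation:
    """Segment via h-maxima markers of the filtered image.

    Cell interiors are brighter than borders, so the regional maxima of the
    ASF-filtered image (with prominence at least ``h``) mark the cells; the
    watershed floods the complement of the filtered image so interiors are
    catchment basins.
    """
    img = _check_image(img)
    filtered = morpho.alternate_sequential_filter(img, p.o)
    markers = morpho.h_maxima_markers(filtered, p.h)
    if not markers.any():
        raise SegmentationError(
            "no h-maxima markers found (h too large or image over-filtered)"
        )
    return _finish(-filtered, markers)


def segment_angulo_matou(img: np.ndarray, p: ParameterSetAM) -> Segmentation:
    """Segment via distance-map markers of a first border estimate.

    Pipeline: opening (``s1``) → Gaussian smoothing (``g``) → black top-hat
    (``s2``) → threshold at ``t`` giving a candidate border set; the
    distance map to that set is computed, its h-maxima (depth ``h``) are
    the cell markers, and the watershed floods the complement of the
    distance map.  ``s2 = 0`` bypasses the top-hat (the threshold then
    applies to the complement of the smoothed image); ``h = 0`` uses the
    raw maxima of the distance map.
    """
    img = _check_image(img)
    filtered = img
    if p.s1 > 0:
        filtered = morpho.opening(filtered, morpho.disk_footprint(int(p.s1)))
    if p.g > 0:
        filtered = ndimage.gaussian_filter(filtered, p.g, mode="reflect")
    if p.s2 > 0:
        response = morpho.top_hat(filtered, int(p.s2), dark=True)
    else:
        response = filtered.max() - filtered
        response -= response.min()
    border = response >= p.t
    if not border.any():
        raise SegmentationError(
            "threshold produced an empty border estimate (t too large)"
        )
    dist = morpho.distance_map(border)
    markers = morpho.h_maxima_markers(dist, p.h)
    if not markers.any():
        raise SegmentationError("no distance-map markers found")
    return _finish(-dist, markers)


def segment_gavet_pinoli(
    img: np.ndarray, p: ParameterSetGP, orientations: int = 8
) -> Segmentation:
    """Segment via linear-contour extraction and skeleton pruning.

    Pipeline: ASF of order ``o`` → complement (borders become bright) →
    supremum of openings by segments of length ``t_s`` → automatic (Otsu)
    threshold → closing by a disk of radius ``c`` → skeletonization with
    pruning of the non-linear parts (again at length ``t_s``), giving a
    rough linear contour set; the distance map to that set, opened by a
    disk of radius ``s``, yields the markers (its regional maxima); the
    final watershed then corrects the rough contours by flooding the
    complement of the filtered image, so the contour lines settle on the
    intensity valleys as in the other two methods.
    """
    img = _check_image(img)
    filtered = morpho.alternate_sequential_filter(img, p.o)
    inverted = filtered.max() - filtered
    response = morpho.sup_open_segments(inverted, int(p.t_s), orientations)
    binary = response >= threshold_otsu(response)
    if p.c > 0:
        fp = morpho.disk_footprint(int(p.c))
        binary = ndimage.binary_dilation(binary, structure=fp)
        binary = ndimage.binary_erosion(binary, structure=fp, border_value=1)
    rough = morpho.prune_nonlinear_skeleton(binary, int(p.t_s), orientations)
    if not rough.any():
        raise SegmentationError(
            "skeleton pruning removed every contour pixel (t_s too large)"
        )
    dist = morpho.distance_map(rough)
    if p.s > 0:
        dist = morpho.opening(dist, morpho.disk_footprint(int(p.s)))
    markers = morpho.regional_maxima(dist)
    if not markers.any():
        raise SegmentationError("no markers survive the distance-map opening")
    return _finish(-filtered, markers)


METHODS = {
    "vm": (segment_vincent_masters, ParameterSetVM),
    "am": (segment_angulo_matou, ParameterSetAM),
    "gp": (segment_gavet_pinoli, ParameterSetGP),
}


def segment(img: np.ndarray, method: str, params) -> Segmentation:
    """Dispatch to one of the three segmenters by short method id."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {sorted(METHODS)}")
    func, cls = METHODS[method]
    if isinstance(params, dict):
        params = cls(**params)
    return func(img, params)
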