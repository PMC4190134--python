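"""Morphological operator toolbox shared by the three endothelium segmenters.

All gray-level operators work on 2-D float or uint8 arrays ("gray images");
binary operators take boolean arrays ("contour maps").  Structuring elements
are discrete Euclidean disks ``{(dx, dy): dx² + dy² ≤ r²}`` or Bresenham line
segments.  Filters use reflective padding at the image frame so that no
spurious extrema appear along the borders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import line as _bresenham_line
from skimage.morphology import skeletonize
from skimage.segmentation import watershed as _skimage_watershed


# ---------------------------------------------------------------------------
# structuring elements
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StructuringElement:
    """A disk (radius in pixels) or a line segment (length, orientation).

    Parameters
    ----------
    shape : {"disk", "segment"}
    radius : int
        Disk radius in pixels (disk only); the footprint is the discrete
        Euclidean ball ``dx² + dy² ≤ radius²``.
    length : int
        Segment length in pixels (segment only).
    orientation : float
        Segment orientation in degrees, in ``[0, 180)`` (segment only).
    """

    shape: str
    radius: int = 0
    length: int = 1
    orientation: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in ("disk", "segment"):
            raise ValueError(f"unknown structuring element shape {self.shape!r}")
        if self.shape == "disk" and self.radius < 0:
            raise ValueError("disk radius must be >= 0")
        if self.shape == "segment":
            if self.length < 1:
                raise ValueError("segment length must be >= 1")
            if not 0.0 <= self.orientation < 180.0:
                raise ValueError("segment orientation must lie in [0, 180)")

    def footprint(self) -> np.ndarray:
        if self.shape == "disk":
            return disk_footprint(self.radius)
        return segment_footprint(self.length, self.orientation)


def disk_footprint(radius: int) -> np.ndarray:
    """Discrete Euclidean disk: pixels with ``dx² + dy² ≤ radius²``."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy * yy + xx * xx) <= r * r


def segment_footprint(length: int, orientation_deg: float) -> np.ndarray:
    """Bresenham line segment of the given pixel length and orientation.

    The segment is centred on the footprint origin; orientation 0° is
    horizontal, angles increase counter-clockwise.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    theta = np.deg2rad(orientation_deg)
    half = (length - 1) / 2.0
    dr = -np.sin(theta) * half  # rows grow downward
    dc = np.cos(theta) * half
    r0, c0 = int(round(-dr)), int(round(-dc))
    r1, c1 = int(round(dr)), int(round(dc))
    rr, cc = _bresenham_line(r0, c0, r1, c1)
    rmin, cmin = rr.min(), cc.min()
    fp = np.zeros((rr.max() - rmin + 1, cc.max() - cmin + 1), dtype=bool)
    fp[rr - rmin, cc - cmin] = True
    # point-symmetrize: erosion/dilation pairs then form true openings and
    # closings (anti-extensive / extensive) for every orientation
    return fp | fp[::-1, ::-1]


# ---------------------------------------------------------------------------
# gray-level operators (reflective border handling throughout)
# ---------------------------------------------------------------------------


def erosion(img: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    return ndimage.grey_erosion(img, footprint=footprint, mode="reflect")


def dilation(img: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    return ndimage.grey_dilation(img, footprint=footprint, mode="reflect")


def _pad_compose(img: np.ndarray, footprint: np.ndarray, first, second) -> np.ndarray:
    """Apply two rank filters as one composition on a reflect-padded copy.

    Padding once and cropping keeps the composition a true opening/closing
    of the reflectively extended image, so anti-extensivity (opening) and
    extensivity (closing) hold up to the image frame, which per-call
    reflective padding does not guarantee.
    """
    pr, pc = footprint.shape[0], footprint.shape[1]
    padded = np.pad(np.asarray(img, dtype=np.float64), ((pr, pr), (pc, pc)), mode="reflect")
    out = second(first(padded, footprint=footprint), footprint=footprint)
    return out[pr:-pr, pc:-pc]


def opening(img: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    return _pad_compose(img, footprint, ndimage.grey_erosion, ndimage.grey_dilation)


def closing(img: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    return _pad_compose(img, footprint, ndimage.grey_dilation, ndimage.grey_erosion)


def alternate_sequential_filter(
    img: np.ndarray, order: int, closing_first: bool = True
) -> np.ndarray:
    """Alternate sequential filter with disks of radius 1..order.

    ``order = 0`` is the identity.  The default applies the closing before
    the opening at each scale: the structures of interest here (cell
    borders) are dark and thin, and closings protect them at small radii.
    """
    if order < 0:
        raise ValueError("filter order must be >= 0")
    out = np.asarray(img, dtype=np.float64)
    for i in range(1, int(order) + 1):
        fp = disk_footprint(i)
        if closing_first:
            out = opening(closing(out, fp), fp)
        else:
            out = closing(opening(out, fp), fp)
    return out


def reconstruction_by_dilation(marker: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Morphological reconstruction of ``marker`` under ``mask`` (8-connected)."""
    marker = np.asarray(marker, dtype=np.float64)
    mask = np.asarray(mask, dtype=np.float64)
    if np.any(marker > mask):
        raise ValueError("marker must be <= mask everywhere")
    from skimage.morphology import reconstruction

    return reconstruction(marker, mask, method="dilation")


def h_maxima_markers(img: np.ndarray, h: float) -> np.ndarray:
    """Binary markers from the h-maxima transform.

    Regional maxima of the reconstruction of ``img − h`` under ``img``:
    only maxima whose prominence exceeds ``h`` survive.  ``h = 0`` returns
    the plain regional maxima.
    """
    if h < 0:
        raise ValueError("h must be >= 0")
    img = np.asarray(img, dtype=np.float64)
    if h == 0:
        return regional_maxima(img)
    rec = reconstruction_by_dilation(img - h, img)
    return regional_maxima(rec)


def regional_maxima(img: np.ndarray) -> np.ndarray:
    """Regional maxima (8-connected plateaus with no higher neighbour)."""
    img = np.asarray(img, dtype=np.float64)
    from skimage.morphology import local_maxima

    return local_maxima(img, connectivity=2, allow_borders=True)


def top_hat(img: np.ndarray, size: int, dark: bool = True) -> np.ndarray:
    """Top-hat residue with a disk of radius ``size``.

    ``dark=True`` (black top-hat) returns ``closing − img`` and extracts
    dark thin structures such as cell borders; ``dark=False`` (white
    top-hat) returns ``img − opening``.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    img = np.asarray(img, dtype=np.float64)
    fp = disk_footprint(size)
    if dark:
        return closing(img, fp) - img
    return img - opening(img, fp)


# ---------------------------------------------------------------------------
# binary / distance operators
# ---------------------------------------------------------------------------


def distance_map(binary: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance to the nearest nonzero pixel of ``binary``."""
    binary = np.asarray(binary, dtype=bool)
    if not binary.any():
        raise ValueError("distance map of an empty set is undefined")
    return ndimage.distance_transform_edt(~binary)


def sup_open_segments(
    img: np.ndarray, length: int, orientations: int = 8
) -> np.ndarray:
    """Pointwise supremum of gray-level openings by line segments.

    One opening per orientation (``orientations`` evenly spaced angles over
    [0°, 180°)); retains bright structures that contain a straight segment
    of the given length at some orientation, i.e. linear cell contours.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if orientations < 2:
        raise ValueError("need at least 2 orientations")
    img = np.asarray(img, dtype=np.float64)
    out = None
    for k in range(orientations):
        angle = 180.0 * k / orientations
        op = opening(img, segment_footprint(length, angle))
        out = op if out is None else np.maximum(out, op)
    return out


def prune_nonlinear_skeleton(
    binary: np.ndarray, t_s: int, orientations: int = 8
) -> np.ndarray:
    """Skeletonize and keep only the linear parts.

    The binary input is thinned to an 8-connected 1-px skeleton; a skeleton
    pixel survives iff some foreground line segment of length ``t_s`` fits
    inside the one-pixel tube around the skeleton through it (binary
    sup-of-openings by segments of the dilated skeleton, intersected with
    the skeleton).  The tube absorbs the staircase mismatch between a
    straight skeleton run and the discrete Bresenham segment at the nearest
    sampled orientation, so straight runs survive at every angle, while
    blobs and short spurs of diameter < ``t_s`` vanish.
    """
    binary = np.asarray(binary, dtype=bool)
    if not binary.any():
        return binary.copy()
    skel = skeletonize(binary)
    if t_s <= 1:
        return skel
    ribbon = ndimage.binary_dilation(skel, structure=np.ones((3, 3), dtype=bool))
    out = np.zeros_like(skel)
    for k in range(orientations):
        angle = 180.0 * k / orientations
        fp = segment_footprint(int(t_s), angle)
        # binary opening with zero-padding: segments must fit inside the set
        er = ndimage.binary_erosion(ribbon, structure=fp, border_value=0)
        out |= ndimage.binary_dilation(er, structure=fp, border_value=0)
    return out & skel


def watershed_lines(
    relief: np.ndarray, markers: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Marker-constrained watershed of a relief.

    Parameters
    ----------
    relief : 2-D array
        Topographic surface; catchment basins grow from the markers.
    markers : bool array
        Nonempty binary marker image; each 8-connected component seeds one
        region.

    Returns
    -------
    labels : int array
        Region labels 1..n partitioning the whole domain (watershed-line
        pixels are assigned to their nearest region, lowest label winning
        ties, so the output satisfies the partition property).
    lines : bool array
        The 1-px watershed-line set separating distinct regions.
    """
    markers = np.asarray(markers, dtype=bool)
    if not markers.any():
        raise ValueError("watershed requires at least one marker")
    marker_labels, n = ndimage.label(markers, structure=np.ones((3, 3), dtype=int))
    ws = _skimage_watershed(
        np.asarray(relief, dtype=np.float64),
        markers=marker_labels,
        watershed_line=True,
    )
    lines = ws == 0
    labels = _fill_zero_labels(ws)
    return labels, lines


def _fill_zero_labels(labels: np.ndarray) -> np.ndarray:
    """Assign zero-labelled pixels to the nearest nonzero label.

    Ties in distance are broken deterministically by the distance
    transform's feature ordering (scan order), then the result is stable
    under repeated calls.
    """
    if not (labels == 0).any():
        return labels
    ind = ndimage.distance_transform_edt(
        labels == 0, return_distances=False, return_indices=True
    )
    return labels[tuple(ind)]


def labels_to_contours(labels: np.ndarray) -> np.ndarray:
    """1-px contour map of a label image.

    A pixel is a contour pixel iff its label differs from the label of its
    right or lower 4-neighbour, so every inter-region boundary is traced by
    a single one-pixel-wide line.
    """
    labels = np.asarray(labels)
    contours = np.zeros(labels.shape, dtype=bool)
    contours[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    contours[:-1, :] |= labels[:-1, :] != labels[1:, :]
    return contours
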