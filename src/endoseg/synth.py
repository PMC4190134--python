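"""Synthetic corneal-endothelium mosaics with paired ground truth.

A healthy endothelium is a near-hexagonal packing of flat cells; ageing or
trauma makes cell areas more variable (polymegathism) and shapes less
hexagonal (pleomorphism).  The generator reproduces this continuum with a
single knob: cells are the Voronoi regions of seeds on a hexagonal lattice,
each seed displaced by a uniform jitter expressed as a fraction of the
lattice spacing.  Jitter 0 gives the honeycomb (100 % hexagons, equal
areas); larger jitter degrades both indices, as in pathological mosaics.

Rendering imitates the specular-microscope appearance: thin dark borders,
brighter cell interiors, a smooth illumination field (the superposition of
reflections from deeper, darker corneal layers), optical blur and sensor
noise.

All randomness derives from the single seed stored in the spec, split into
one named substream per stochastic step, so a spec renders identically
every time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .morpho import labels_to_contours

# substream indices for the per-step RNGs
_STREAM_JITTER = 0
_STREAM_ILLUMINATION = 1
_STREAM_NOISE = 2


@dataclass(frozen=True)
class SyntheticSpec:
    """Geometry and photometry of one synthetic endothelium image.

    Defaults emulate a typical specular-microscope field at roughly
    0.5 µm/pixel: cells of ~1500 px² (≈375 µm², an ECD near 2700
    cells/mm²), moderate shape irregularity, borders a few pixels wide and
    only ~40 gray levels darker than the interiors, a pronounced smooth
    illumination drift from the superposed corneal layers, optical blur
    and strong sensor noise — specular images are low-contrast and noisy.
    """

    width: int = 256
    height: int = 256
    mean_cell_area: float = 1500.0
    jitter: float = 0.35
    border_width: int = 4
    border_intensity: float = 100.0
    interior_intensity: float = 140.0
    illumination_amplitude: float = 30.0
    noise_sigma: float = 25.0
    blur_sigma: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.jitter <= 1.0:
            raise ValueError("jitter must lie in [0, 1]")
        if self.border_width < 1:
            raise ValueError("border_width must be >= 1")
        if not self.border_intensity < self.interior_intensity:
            raise ValueError(
                "border_intensity must be below interior_intensity "
                "(cell borders are darker than cell interiors)"
            )
        if self.mean_cell_area <= 0:
            raise ValueError("mean_cell_area must be positive")
        if self.width < 1 or self.height < 1:
            raise ValueError("domain must be nonempty")
        if self.mean_cell_area > self.width * self.height:
            raise ValueError("domain too small to hold a single cell")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        return cls(**d)


@dataclass(frozen=True)
class GroundTruth:
    """Reference segmentation of a synthetic mosaic.

    ``labels`` is the cell partition (labels 1..n cover the domain),
    ``contours`` the 1-px closed border set separating distinct labels,
    ``cell_seeds`` the generating (row, col) seed coordinates.
    """

    labels: np.ndarray
    contours: np.ndarray
    cell_seeds: np.ndarray = field(repr=False)

    @property
    def n_cells(self) -> int:
        return int(self.labels.max())


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def hexagonal_seeds(spec: SyntheticSpec) -> np.ndarray:
    """Seed points of a (jittered) hexagonal lattice covering the domain.

    The lattice constant ``a`` is chosen so that the unperturbed Voronoi
    cell (a regular hexagon) has area ``mean_cell_area``:
    ``a = sqrt(2 A / sqrt(3))``.  Per-seed jitter is uniform in
    ``±jitter·a/2`` along each axis.
    """
    a = float(np.sqrt(2.0 * spec.mean_cell_area / np.sqrt(3.0)))
    row_step = a * np.sqrt(3.0) / 2.0
    rng = _rng(spec.seed, _STREAM_JITTER)
    seeds = []
    # extend one lattice ring beyond the frame so border cells are well formed
    r = -row_step
    irow = -1
    while r < spec.height + row_step:
        offset = (a / 2.0) if (irow % 2) else 0.0
        c = -a + offset
        while c < spec.width + a:
            seeds.append((r, c))
            c += a
        r += row_step
        irow += 1
    seeds = np.asarray(seeds, dtype=np.float64)
    if spec.jitter > 0:
        seeds = seeds + rng.uniform(
            -spec.jitter * a / 2.0, spec.jitter * a / 2.0, size=seeds.shape
        )
    return seeds


def generate_mosaic(spec: SyntheticSpec) -> GroundTruth:
    """Voronoi mosaic of jittered hexagonal-lattice seeds.

    Deterministic given ``spec.seed``.  Labels are renumbered 1..n over the
    seeds that actually own at least one pixel; contours are the 1-px
    boundary set between distinct labels.
    """
    seeds = hexagonal_seeds(spec)
    rows, cols = np.mgrid[0 : spec.height, 0 : spec.width]
    pts = np.column_stack([rows.ravel(), cols.ravel()]).astype(np.float64)
    _, owner = cKDTree(seeds).query(pts, k=1)
    labels = owner.reshape(spec.height, spec.width)
    # renumber to consecutive 1..n and keep only seeds that own pixels
    present, labels = np.unique(labels, return_inverse=True)
    labels = labels.reshape(spec.height, spec.width).astype(np.int32) + 1
    contours = labels_to_contours(labels)
    return GroundTruth(
        labels=labels, contours=contours, cell_seeds=seeds[present]
    )


def render_specular(truth: GroundTruth, spec: SyntheticSpec) -> np.ndarray:
    """Render a mosaic as an 8-bit-range specular-microscopy-like image.

    Borders (contours dilated to ``border_width``) take the dark border
    intensity, interiors the brighter interior intensity; a smooth additive
    illumination field (two low-frequency sinusoids with seeded random
    orientation and phase), Gaussian blur and additive Gaussian noise
    follow; the result is clipped to [0, 255].  Pure function of
    ``(truth, spec)``.
    """
    h, w = truth.labels.shape
    border = truth.contours
    if spec.border_width > 1:
        border = ndimage.binary_dilation(
            border, iterations=int(spec.border_width) - 1
        )
    img = np.where(border, spec.border_intensity, spec.interior_intensity).astype(
        np.float64
    )
    if spec.illumination_amplitude > 0:
        rng = _rng(spec.seed, _STREAM_ILLUMINATION)
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
        field = np.zeros((h, w))
        for _ in range(2):
            theta = rng.uniform(0, np.pi)
            phase = rng.uniform(0, 2 * np.pi)
            # wavelength comparable to the field of view: smooth drift
            wavelength = rng.uniform(0.7, 1.5) * max(h, w)
            u = np.cos(theta) * xx + np.sin(theta) * yy
            field += np.sin(2 * np.pi * u / wavelength + phase)
        field *= spec.illumination_amplitude / 4.0  # two unit sinusoids
        img = img + field
    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma, mode="reflect")
    if spec.noise_sigma > 0:
        rng = _rng(spec.seed, _STREAM_NOISE)
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return np.clip(img, 0.0, 255.0)


def perturb_contours(
    contours: np.ndarray,
    translation: tuple[int, int] = (0, 0),
    flip_rate: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Simulate intra-expert redrawing variability of a contour map.

    The map is translated by ``translation = (drow, dcol)`` (content shifted
    inside the frame, vacated pixels empty) and a fraction ``flip_rate`` of
    the contour pixels is then displaced to a random free neighbouring
    position at Chebyshev distance ≤ 1.  Deterministic given ``seed``.
    """
    contours = np.asarray(contours, dtype=bool)
    if not contours.any():
        raise ValueError("cannot perturb an empty contour map")
    if not 0.0 <= flip_rate <= 1.0:
        raise ValueError("flip_rate must lie in [0, 1]")
    out = np.zeros_like(contours)
    dr, dc = int(translation[0]), int(translation[1])
    h, w = contours.shape
    src = contours[
        max(0, -dr) : h - max(0, dr), max(0, -dc) : w - max(0, dc)
    ]
    out[max(0, dr) : h + min(0, dr), max(0, dc) : w + min(0, dc)] = src
    if flip_rate > 0:
        rng = np.random.default_rng(seed)
        pix = np.argwhere(out)
        n_move = int(round(flip_rate * len(pix)))
        chosen = pix[rng.choice(len(pix), size=n_move, replace=False)]
        offsets = [(a, b) for a in (-1, 0, 1) for b in (-1, 0, 1) if (a, b) != (0, 0)]
        for r, c in chosen:
            cand = [
                (r + a, c + b)
                for a, b in offsets
                if 0 <= r + a < h and 0 <= c + b < w and not out[r + a, c + b]
            ]
            if not cand:
                continue  # fully surrounded: leave the pixel in place
            rr, cc = cand[rng.integers(len(cand))]
            out[r, c] = False
            out[rr, cc] = True
    return out
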