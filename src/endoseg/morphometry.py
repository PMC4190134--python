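"""Clinical morphometry of a segmented endothelium.

Three indices summarise the health of the cell mosaic:

* ECD — endothelial cell density in cells/mm².  Below 1000 cells/mm² an
  intraocular lens implant is contraindicated; below 400 cells/mm² the
  endothelial pump can no longer keep the cornea transparent.
* polymegathism — coefficient of variation of cell areas (percent); low
  values mean uniformly sized cells.
* pleomorphism — percentage of hexagon-like cells, operationalised as
  cells with exactly six neighbours in the region-adjacency graph; a
  healthy mosaic is close to a honeycomb.

Cells touching the image frame have truncated areas and adjacencies and
are excluded from every index.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

ECD_TRANSPARENCY_THRESHOLD = 400.0  # cells/mm²
ECD_IMPLANT_THRESHOLD = 1000.0  # cells/mm²


@dataclass(frozen=True)
class MorphometryReport:
    ecd: float  # cells/mm²
    polymegathism: float  # percent (CV of areas)
    pleomorphism: float  # percent of hexagon-like cells
    n_cells: int
    pixel_size: float  # mm/pixel
    below_transparency_threshold: bool = False
    below_implant_threshold: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def interior_labels(labels: np.ndarray) -> np.ndarray:
    """Labels of cells that do not touch the image frame (label 0, if
    present, denotes background/border and is never a cell)."""
    labels = np.asarray(labels)
    frame = np.unique(
        np.concatenate(
            [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
        )
    )
    all_labels = np.unique(labels)
    keep = np.setdiff1d(all_labels, frame)
    return keep[keep > 0]


def _areas(labels: np.ndarray, which: np.ndarray) -> np.ndarray:
    counts = np.bincount(labels.ravel(), minlength=int(labels.max()) + 1)
    return counts[which].astype(float)


def adjacency_counts(labels: np.ndarray, which: np.ndarray) -> dict[int, int]:
    """Number of neighbours of each requested cell in the region-adjacency
    graph built from 4-adjacent pixel pairs with distinct labels."""
    labels = np.asarray(labels)
    pairs = set()
    a, b = labels[:, :-1], labels[:, 1:]
    m = a != b
    pairs.update(zip(a[m].tolist(), b[m].tolist()))
    a, b = labels[:-1, :], labels[1:, :]
    m = a != b
    pairs.update(zip(a[m].tolist(), b[m].tolist()))
    neighbours: dict[int, set] = {int(l): set() for l in which}
    for u, v in pairs:
        if u in neighbours and v != 0:
            neighbours[u].add(v)
        if v in neighbours and u != 0:
            neighbours[v].add(u)
    return {l: len(s) for l, s in neighbours.items()}


def cell_density(labels: np.ndarray, pixel_size: float) -> float:
    """ECD in cells/mm²: included cell count over their total area."""
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    keep = interior_labels(labels)
    if len(keep) == 0:
        raise ValueError("no cell avoids the image frame")
    areas_mm2 = _areas(labels, keep) * pixel_size**2
    return float(len(keep) / areas_mm2.sum())


def polymegathism(labels: np.ndarray) -> float:
    """Coefficient of variation of included cell areas, in percent."""
    keep = interior_labels(labels)
    if len(keep) < 2:
        raise ValueError("need at least two frame-free cells")
    areas = _areas(labels, keep)
    return float(100.0 * areas.std() / areas.mean())


def pleomorphism(labels: np.ndarray) -> float:
    """Percentage of included cells with exactly six adjacent cells."""
    keep = interior_labels(labels)
    if len(keep) == 0:
        raise ValueError("no cell avoids the image frame")
    counts = adjacency_counts(labels, keep)
    hexa = sum(1 for l in keep if counts[int(l)] == 6)
    return float(100.0 * hexa / len(keep))


def report(labels: np.ndarray, pixel_size: float) -> MorphometryReport:
    """Full morphometry report with the clinical threshold flags."""
    ecd = cell_density(labels, pixel_size)
    keep = interior_labels(labels)
    poly = polymegathism(labels) if len(keep) >= 2 else float("nan")
    return MorphometryReport(
        ecd=ecd,
        polymegathism=poly,
        pleomorphism=pleomorphism(labels),
        n_cells=int(len(keep)),
        pixel_size=float(pixel_size),
        below_transparency_threshold=bool(ecd < ECD_TRANSPARENCY_THRESHOLD),
        below_implant_threshold=bool(ecd < ECD_IMPLANT_THRESHOLD),
    )
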