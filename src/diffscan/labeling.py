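"""Scan-point class labels from region-of-interest polygons.

Ground truth for training comes from polygons drawn over the integrated
image of a scan area: polygons select amorphous-ice and crystalline-ice
regions, everything else defaults to carbon, and a "mixed" band is added
along every class boundary because the beam footprint (which overlaps
neighbouring scan points by ~39%) straddles both materials there.

Class encoding is fixed package-wide: carbon=0, amorphous_ice=1,
crystalline_ice=2, mixed=3.  Polygon vertices are ``(x, y)`` pairs in
scan-grid coordinates, x = column, y = row, with scan points at integer
coordinates.
"""

from __future__ import annotations

import json
from enum import IntEnum

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Polygon

__all__ = [
    "ClassLabel",
    "CLASS_NAMES",
    "PURE_CLASSES",
    "rasterize_roi",
    "assign_labels",
    "load_rois",
    "save_rois",
    "save_class_map",
    "load_class_map",
]


class ClassLabel(IntEnum):
    """The four scan-point classes, in fixed tie-break order."""

    carbon = 0
    amorphous_ice = 1
    crystalline_ice = 2
    mixed = 3


CLASS_NAMES = tuple(c.name for c in ClassLabel)
PURE_CLASSES = (ClassLabel.carbon, ClassLabel.amorphous_ice, ClassLabel.crystalline_ice)


def rasterize_roi(vertices, grid_shape: tuple[int, int]) -> np.ndarray:
    """Boolean scan-grid mask of a polygon: point-in-polygon at each scan
    point centre, boundary points counting as inside.

    Parameters
    ----------
    vertices : sequence of (x, y)
        Polygon vertices in scan-grid coordinates (x = column, y = row).
    grid_shape : (rows, cols)
    """
    vertices = np.asarray(vertices, dtype=float)
    if vertices.ndim != 2 or vertices.shape[0] < 3 or vertices.shape[1] != 2:
        raise ValueError("a polygon needs at least 3 (x, y) vertices")
    rows, cols = grid_shape
    poly = Polygon(vertices)
    yy, xx = np.mgrid[0:rows, 0:cols]
    pts = shapely.points(xx.ravel().astype(float), yy.ravel().astype(float))
    inside = shapely.covers(poly, pts)
    return inside.reshape(rows, cols)


def assign_labels(
    ice_masks,
    crystalline_masks,
    mixed_band: int,
    grid_shape: tuple[int, int],
) -> np.ndarray:
    """Combine ROI masks into a per-scan-point class map.

    Priority on overlap is crystalline_ice > amorphous_ice > carbon; then
    every point within Chebyshev distance ``mixed_band`` of a boundary
    between two classes is relabelled mixed.  ``mixed_band = 0`` produces no
    mixed labels.
    """
    if mixed_band < 0:
        raise ValueError("mixed_band must be >= 0")
    rows, cols = grid_shape
    labels = np.full((rows, cols), int(ClassLabel.carbon), dtype=np.int8)
    for m in ice_masks:
        m = np.asarray(m, dtype=bool)
        if m.shape != (rows, cols):
            raise ValueError(f"mask shape {m.shape} != grid shape {grid_shape}")
        labels[m] = int(ClassLabel.amorphous_ice)
    for m in crystalline_masks:
        m = np.asarray(m, dtype=bool)
        if m.shape != (rows, cols):
            raise ValueError(f"mask shape {m.shape} != grid shape {grid_shape}")
        labels[m] = int(ClassLabel.crystalline_ice)
    if mixed_band > 0:
        size = 2 * mixed_band + 1
        lo = ndimage.minimum_filter(labels, size=size, mode="nearest")
        hi = ndimage.maximum_filter(labels, size=size, mode="nearest")
        labels[lo != hi] = int(ClassLabel.mixed)
    return labels


def load_rois(path):
    """Read ROI polygons from JSON: a list of ``{"label", "vertices"}``."""
    with open(path) as fh:
        entries = json.load(fh)
    out = []
    for e in entries:
        label = ClassLabel[e["label"]]
        if label not in (ClassLabel.amorphous_ice, ClassLabel.crystalline_ice):
            raise ValueError(f"ROI label must be an ice class, got {label.name}")
        out.append((label, np.asarray(e["vertices"], dtype=float)))
    return out


def save_rois(path, rois) -> None:
    entries = [
        {"label": ClassLabel(label).name, "vertices": np.asarray(v, dtype=float).tolist()}
        for label, v in rois
    ]
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=1)


def save_class_map(path, labels: np.ndarray) -> None:
    """Class map as integer-grid CSV with the label legend in a header."""
    legend = ", ".join(f"{int(c)}={c.name}" for c in ClassLabel)
    np.savetxt(path, labels, fmt="%d", delimiter=",", header=f"classes: {legend}")


def load_class_map(path) -> np.ndarray:
    return np.loadtxt(path, dtype=np.int8, delimiter=",")
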