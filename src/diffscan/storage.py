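"""File formats: HDF5 scan datasets, TIFF/CSV interchange, feature tables.

HDF5 is the canonical container — one file per scan with the frame stack,
labels, true centres, gain map, invalid-pixel mask, geometry and provenance
attributes.  Interchange exports are a multi-page TIFF of the frames plus a
plain-text label table, CSV tables for RIA profiles and refined centres, and
HDF5 for PCC matrices.  Every writer has a reader that round-trips
losslessly.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import tifffile

from .geometry import DetectorGeometry, ScanGeometry
from .labeling import CLASS_NAMES
from .simulate import ScanDataset

__all__ = [
    "write_dataset",
    "read_dataset",
    "export_tiff",
    "write_label_table",
    "read_label_table",
    "write_ria_csv",
    "read_ria_csv",
    "write_centers_table",
    "read_centers_table",
    "write_pcc",
    "read_pcc",
]


def write_dataset(path, ds: ScanDataset) -> None:
    """Write a ScanDataset to HDF5 (frames lzf-compressed)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=ds.frames, compression="lzf")
        f.create_dataset("labels", data=ds.labels)
        f.create_dataset("true_centers", data=ds.true_centers)
        f.create_dataset("gain_map", data=ds.gain_map)
        f.create_dataset("invalid_mask", data=ds.invalid_mask)
        f.attrs["geometry"] = json.dumps(ds.geometry.to_dict())
        f.attrs["scan_geometry"] = json.dumps(ds.scan_geometry.to_dict())
        f.attrs["seed"] = -1 if ds.seed is None else ds.seed
        f.attrs["metadata"] = json.dumps(ds.metadata)
        f.attrs["class_names"] = json.dumps(list(CLASS_NAMES))


def read_dataset(path) -> ScanDataset:
    with h5py.File(path, "r") as f:
        seed = int(f.attrs["seed"])
        return ScanDataset(
            frames=f["frames"][()],
            labels=f["labels"][()],
            true_centers=f["true_centers"][()],
            gain_map=f["gain_map"][()],
            invalid_mask=f["invalid_mask"][()].astype(bool),
            geometry=DetectorGeometry.from_dict(json.loads(f.attrs["geometry"])),
            scan_geometry=ScanGeometry.from_dict(json.loads(f.attrs["scan_geometry"])),
            seed=None if seed == -1 else seed,
            metadata=json.loads(f.attrs["metadata"]),
        )


def export_tiff(path, ds: ScanDataset) -> None:
    """Frames as a multi-page TIFF stack in row-major scan order."""
    tifffile.imwrite(path, ds.flat_frames(), photometric="minisblack")


def write_label_table(path, labels: np.ndarray) -> None:
    """Plain-text label table: row, col, label name."""
    rows, cols = labels.shape
    with open(path, "w") as fh:
        fh.write("row\tcol\tlabel\n")
        for r in range(rows):
            for c in range(cols):
                fh.write(f"{r}\t{c}\t{CLASS_NAMES[int(labels[r, c])]}\n")


def read_label_table(path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            r, c, name = line.split()
            rows.append((int(r), int(c), CLASS_NAMES.index(name)))
    nr = max(r for r, _, _ in rows) + 1
    nc = max(c for _, c, _ in rows) + 1
    out = np.zeros((nr, nc), dtype=np.int8)
    for r, c, v in rows:
        out[r, c] = v
    return out


def write_ria_csv(path, profiles: np.ndarray, labels: np.ndarray) -> None:
    """One row per scan point: row, col, label, then the RIA values."""
    rows, cols = labels.shape
    n_bins = profiles.shape[-1]
    flat = profiles.reshape(rows * cols, n_bins)
    with open(path, "w") as fh:
        fh.write("row,col,label," + ",".join(f"bin{i}" for i in range(n_bins)) + "\n")
        for r in range(rows):
            for c in range(cols):
                vals = ",".join(repr(float(v)) for v in flat[r * cols + c])
                fh.write(f"{r},{c},{int(labels[r, c])},{vals}\n")


def read_ria_csv(path):
    data = np.genfromtxt(path, delimiter=",", skip_header=1)
    data = np.atleast_2d(data)
    rr = data[:, 0].astype(int)
    cc = data[:, 1].astype(int)
    nr, nc = rr.max() + 1, cc.max() + 1
    labels = np.zeros((nr, nc), dtype=np.int8)
    labels[rr, cc] = data[:, 2].astype(np.int8)
    profiles = np.full((nr * nc, data.shape[1] - 3), np.nan)
    profiles[rr * nc + cc] = data[:, 3:]
    return profiles, labels


def write_centers_table(path, centers: np.ndarray, residuals: np.ndarray | None = None) -> None:
    """Refined beam centres as plain text: row, col, x, y[, residual]."""
    rows, cols = centers.shape[:2]
    with open(path, "w") as fh:
        fh.write("row\tcol\tx\ty\tresidual_x\tresidual_y\n")
        for r in range(rows):
            for c in range(cols):
                x, y = (float(v) for v in centers[r, c])
                rx, ry = (0.0, 0.0) if residuals is None else (float(v) for v in residuals[r, c])
                fh.write(f"{r}\t{c}\t{x!r}\t{y!r}\t{rx!r}\t{ry!r}\n")


def read_centers_table(path):
    data = np.loadtxt(path, skiprows=1)
    data = np.atleast_2d(data)
    nr = int(data[:, 0].max()) + 1
    nc = int(data[:, 1].max()) + 1
    centers = np.zeros((nr, nc, 2))
    residuals = np.zeros((nr, nc, 2))
    for row in data:
        r, c = int(row[0]), int(row[1])
        centers[r, c] = row[2:4]
        residuals[r, c] = row[4:6]
    return centers, residuals


def write_pcc(path, matrix: np.ndarray, grid_shape: tuple[int, int]) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("pcc", data=matrix, compression="lzf")
        f.attrs["grid_shape"] = list(grid_shape)


def read_pcc(path):
    with h5py.File(path, "r") as f:
        return f["pcc"][()], tuple(int(v) for v in f.attrs["grid_shape"])
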