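"""Frame features: binned radial intensity averages and the Pearson
cross-correlation matrix.

RIA (radial intensity average) reduces a recentred frame to the mean
intensity in concentric 1-pixel annuli around the beam centre — 516 values
for a 1032-pixel canvas instead of 512×512 = 262 144 pixels — exploiting the
isotropy of amorphous diffraction.  PCC treats each frame as a variable
observed over its pixels and correlates every frame with every other frame
of the same scan, giving a symmetric N×N matrix (1600×1600 for a 40×40
grid) whose rows, reshaped to the scan grid, map out regions of similar
material.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import CenteredFrame

__all__ = ["RIAProfile", "radial_average", "pcc_matrix", "pcc_slice"]


@dataclass
class RIAProfile:
    """Radial intensity average: per-annulus mean intensity and the number
    of valid pixels that fell in each annulus.  ``values`` is NaN where
    ``counts`` is 0 (annulus empty — e.g. beyond the frame corners)."""

    values: np.ndarray
    counts: np.ndarray
    bin_width: float = 1.0

    def __len__(self) -> int:
        return len(self.values)


def radial_average(
    frame: CenteredFrame,
    n_bins: int | None = None,
    bin_width: float = 1.0,
    use_subpixel_center: bool = True,
) -> RIAProfile:
    """Binned radial average of a recentred frame.

    Every valid pixel (pixel centres on an integer mesh grid) is assigned to
    annulus ``floor(r / bin_width)`` by its Euclidean distance ``r`` to the
    beam centre; per-annulus intensities are summed and averaged; invalid
    pixels (off-detector canvas, tiling cross) are discarded, as are annuli
    beyond ``n_bins − 1``.  By default the refined sub-pixel centre is used;
    ``use_subpixel_center=False`` bins around the integer canvas centre.
    """
    canvas_n = frame.pixels.shape[0]
    if n_bins is None:
        n_bins = canvas_n // 2
    if not frame.valid_mask.any():
        raise ValueError("frame has no valid pixels")
    cx, cy = frame.subpixel_center() if use_subpixel_center else frame.canvas_center
    ys, xs = np.nonzero(frame.valid_mask)
    r = np.hypot(xs - cx, ys - cy)
    bins = (r / bin_width).astype(np.int64)
    keep = bins < n_bins
    bins = bins[keep]
    vals = frame.pixels[ys[keep], xs[keep]]
    sums = np.bincount(bins, weights=vals, minlength=n_bins)
    counts = np.bincount(bins, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return RIAProfile(values=values, counts=counts.astype(np.int64), bin_width=bin_width)


def pcc_matrix(frames: np.ndarray, valid_mask: np.ndarray | None = None) -> np.ndarray:
    """Pearson cross-correlation matrix of a stack of frames.

    Frames are the variables, pixels the observations: entry (i, j) is the
    mean-centred covariance of frames i and j over pixels, normalised by the
    two standard deviations.  A constant frame has undefined correlation and
    yields a NaN row/column (diagonal included) rather than an error.

    Parameters
    ----------
    frames : (N, ...) array
        N frames, each flattened over its remaining axes.  Computation runs
        in the input floating dtype (pass float32 for large stacks).
    valid_mask : bool array, optional
        Pixel mask applied to every frame (e.g. to exclude the tiling
        cross); only pixels valid everywhere enter the correlation.
    """
    X = np.asarray(frames)
    if X.ndim < 2 or X.shape[0] < 2:
        raise ValueError("need at least two frames")
    N = X.shape[0]
    X = X.reshape(N, -1)
    if valid_mask is not None:
        X = X[:, np.asarray(valid_mask, bool).ravel()]
    if X.shape[1] < 2:
        raise ValueError("need at least two pixels per frame")
    if not np.issubdtype(X.dtype, np.floating):
        X = X.astype(np.float64)
    constant = X.max(axis=1) == X.min(axis=1)
    Xc = X - X.mean(axis=1, keepdims=True)
    cov = Xc @ Xc.T
    var = np.diag(cov).copy()
    var[constant] = 0.0
    sd = np.sqrt(var, where=var > 0, out=np.zeros_like(var, dtype=np.float64))
    with np.errstate(invalid="ignore", divide="ignore"):
        M = cov / np.outer(sd, sd)
    M = np.asarray(M, dtype=np.float64)
    M[var == 0, :] = np.nan
    M[:, var == 0] = np.nan
    np.clip(M, -1.0, 1.0, out=M)
    defined = np.flatnonzero(var > 0)
    M[defined, defined] = 1.0
    return M


def pcc_slice(matrix: np.ndarray, scan_position: tuple[int, int], grid_shape: tuple[int, int]) -> np.ndarray:
    """One row of the PCC matrix reshaped onto the scan grid (row-major).

    The map shows how strongly the frame at ``scan_position`` correlates
    with every other scan point; the self-entry at the queried position is 1.
    """
    rows, cols = grid_shape
    r, c = scan_position
    if not (0 <= r < rows and 0 <= c < cols):
        raise ValueError(f"scan position {scan_position} outside grid {grid_shape}")
    if matrix.shape != (rows * cols, rows * cols):
        raise ValueError("matrix size does not match grid")
    return matrix[r * cols + c].reshape(rows, cols)
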