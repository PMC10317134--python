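"""Gain correction, beam-centre refinement and frame recentring.

The direct beam wanders over the detector during a scan (no descan
correction), so before radial features can be computed every frame's beam
centre is located and the frame is moved onto a double-size canvas with the
beam at the canvas centre.  The shift is integer-pixel — count data are
moved, never resampled — and the sub-pixel residual is carried alongside so
radial binning can still use the refined sub-pixel centre.

Coordinate convention (used package-wide): 0-based pixel indices, pixel
centres at integer coordinates, centres as ``(x, y)`` with x = column and
y = row.  A 512-pixel frame recentres onto a 1032×1032 canvas whose centre
is (516, 516).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import canvas_size

__all__ = [
    "BeamCenter",
    "CenteredFrame",
    "PeakNotFoundError",
    "gain_correct",
    "find_beam_center",
    "center_frame",
    "uncenter_frame",
]


class PeakNotFoundError(RuntimeError):
    """Raised when a frame has no above-threshold peak to centre on."""


@dataclass(frozen=True)
class BeamCenter:
    """Sub-pixel beam-centre estimate, x = column, y = row."""

    x: float
    y: float

    def __iter__(self):
        return iter((self.x, self.y))


@dataclass
class CenteredFrame:
    """A frame placed on the recentring canvas.

    ``pixels`` is the canvas (invalid pixels hold 0 but must never enter
    statistics — use ``valid_mask``); ``valid_mask`` is True exactly where an
    original, unflagged detector pixel landed; ``residual`` is the sub-pixel
    part of the shift, so the refined beam centre sits at
    ``canvas_center + residual``.
    """

    pixels: np.ndarray
    valid_mask: np.ndarray
    residual: tuple[float, float]

    @property
    def canvas_center(self) -> tuple[float, float]:
        c = self.pixels.shape[0] // 2
        return (float(c), float(c))

    def subpixel_center(self) -> tuple[float, float]:
        cx, cy = self.canvas_center
        return (cx + self.residual[0], cy + self.residual[1])


def gain_correct(pixels: np.ndarray, gain_map: np.ndarray) -> np.ndarray:
    """Flat-field correction: per-pixel division by the gain map.

    The gain map must be strictly positive and frame-shaped; the first
    offending pixel is named otherwise.  Invalid-pixel flags (the tiling
    cross) are tracked separately and are unaffected by division.
    """
    pixels = np.asarray(pixels)
    gain_map = np.asarray(gain_map)
    if gain_map.shape != pixels.shape:
        raise ValueError(f"gain map shape {gain_map.shape} != frame shape {pixels.shape}")
    bad = gain_map <= 0
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(f"non-positive gain value {gain_map[r, c]!r} at pixel (row={r}, col={c})")
    return pixels.astype(np.float64) / gain_map


def find_beam_center(
    pixels: np.ndarray,
    median_size: int = 3,
    gaussian_sigma: float = 2.0,
    threshold: float = 0.25,
    window: int = 19,
    invalid_mask: np.ndarray | None = None,
    coarse_window: int | None = 128,
) -> BeamCenter:
    """Locate the direct beam as the strongest smoothed local maximum, with
    sub-pixel refinement.

    Invalid pixels (the tiling cross, which typically runs right past the
    beam) are first inpainted by normalized Gaussian convolution, the result
    is median-then-Gaussian smoothed, pixels below ``threshold``·max are
    discarded, and the sub-pixel position comes from a weighted
    least-squares paraboloid fit to the log intensity in a ``window``-sized
    box around the strongest maximum, using only originally valid pixels.
    The log-paraboloid fit is exact for a Gaussian peak and — unlike a plain
    intensity centroid — stays unbiased when the cross clips one side of the
    peak.  Falls back to an intensity-weighted centroid if the fit is not
    concave.  As long as the direct-beam amplitude exceeds every Bragg-spot
    amplitude this returns the beam, not a spot.

    For speed on large frames the filtering runs on a ``coarse_window``-sized
    box around a coarse (4×4 block-mean argmax) beam estimate; the direct
    beam dominates every other feature by an order of magnitude, so the
    coarse stage cannot lock onto a Bragg spot.  Pass ``coarse_window=None``
    to filter the whole frame.
    """
    full = np.asarray(pixels, dtype=np.float64)
    fy, fx = full.shape
    x_off = y_off = 0
    img = full
    full_invalid = invalid_mask
    if coarse_window is not None and min(fy, fx) > coarse_window:
        b = 4
        hy, hx = (fy // b) * b, (fx // b) * b
        work = full[:hy, :hx]
        if invalid_mask is not None:
            work = np.where(np.asarray(invalid_mask, bool)[:hy, :hx], 0.0, work)
        coarse = work.reshape(hy // b, b, hx // b, b).mean(axis=(1, 3))
        cy_b, cx_b = np.unravel_index(np.argmax(coarse), coarse.shape)
        half = coarse_window // 2
        y_off = int(np.clip(cy_b * b + b // 2 - half, 0, fy - coarse_window))
        x_off = int(np.clip(cx_b * b + b // 2 - half, 0, fx - coarse_window))
        img = full[y_off : y_off + coarse_window, x_off : x_off + coarse_window]
        if invalid_mask is not None:
            full_invalid = np.asarray(invalid_mask, bool)[
                y_off : y_off + coarse_window, x_off : x_off + coarse_window
            ]
    ny, nx = img.shape
    invalid_mask = full_invalid
    if invalid_mask is None:
        valid = np.ones(img.shape, dtype=bool)
        filled = img
    else:
        valid = ~np.asarray(invalid_mask, bool)
        v = valid.astype(float)
        est = ndimage.gaussian_filter(img * v, 3.0) / np.maximum(ndimage.gaussian_filter(v, 3.0), 1e-6)
        filled = np.where(valid, img, est)
    sm = ndimage.gaussian_filter(ndimage.median_filter(filled, size=median_size), sigma=gaussian_sigma)
    peak = sm.max()
    if peak <= 0:
        raise PeakNotFoundError("no positive intensity after smoothing")
    py, px = np.unravel_index(np.argmax(sm), sm.shape)
    h = window // 2
    y0, y1 = max(py - h, 0), min(py + h + 1, ny)
    x0, x1 = max(px - h, 0), min(px + h + 1, nx)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    w = sm[y0:y1, x0:x1]
    use = valid[y0:y1, x0:x1] & (w > threshold * peak)
    if not use.any():
        raise PeakNotFoundError("no valid above-threshold pixels around the peak")
    weights = (w * use).ravel() ** 2
    x = (xx - px).astype(float).ravel()
    y = (yy - py).astype(float).ravel()
    z = np.log(np.maximum(w, 1e-12)).ravel()
    A = np.stack([np.ones_like(x), x, y, x * x, y * y], axis=-1)
    try:
        coef = np.linalg.solve(A.T @ (A * weights[:, None]), A.T @ (weights * z))
        _, b, c, d, e = coef
        ok = np.isfinite(coef).all() and d < 0 and e < 0
        cx, cy = px - b / (2 * d), py - c / (2 * e)
        ok = ok and abs(cx - px) <= h and abs(cy - py) <= h
    except np.linalg.LinAlgError:
        ok = False
    if not ok:  # degenerate fit → plain centroid over valid above-threshold pixels
        wp = w * use
        cx = float((wp * xx).sum() / wp.sum())
        cy = float((wp * yy).sum() / wp.sum())
    return BeamCenter(
        x=float(np.clip(cx, 0, nx - 1)) + x_off,
        y=float(np.clip(cy, 0, ny - 1)) + y_off,
    )


def _round_half_up(v: float) -> int:
    return int(np.floor(v + 0.5))


def center_frame(
    pixels: np.ndarray,
    center: BeamCenter | tuple[float, float],
    invalid_mask: np.ndarray | None = None,
) -> CenteredFrame:
    """Place a frame on the double-size canvas with the beam at the centre.

    The shift is integer-pixel: the pixel containing the rounded centre
    lands exactly on the canvas centre, and the sub-pixel remainder is
    returned as ``residual``.  Pixel values are moved, never interpolated,
    so the sum of valid pixels is conserved.  A frame centred at
    (255.5, 255.5) occupies canvas rows/cols [260, 772).
    """
    pixels = np.asarray(pixels)
    n = pixels.shape[0]
    if pixels.shape != (n, n):
        raise ValueError("frame must be square")
    cx, cy = tuple(center)
    if not (0 <= cx < n and 0 <= cy < n):
        raise ValueError(f"centre ({cx}, {cy}) outside frame bounds")
    canvas_n = canvas_size(n)
    target = canvas_n // 2
    icx, icy = _round_half_up(cx), _round_half_up(cy)
    x0, y0 = target - icx, target - icy
    if x0 < 0 or y0 < 0 or x0 + n > canvas_n or y0 + n > canvas_n:
        raise ValueError("shift would push the frame off the canvas")
    canvas = np.zeros((canvas_n, canvas_n), dtype=np.float64)
    canvas[y0 : y0 + n, x0 : x0 + n] = pixels
    valid = np.zeros((canvas_n, canvas_n), dtype=bool)
    valid[y0 : y0 + n, x0 : x0 + n] = True if invalid_mask is None else ~np.asarray(invalid_mask, bool)
    return CenteredFrame(pixels=canvas, valid_mask=valid, residual=(cx - icx, cy - icy))


def uncenter_frame(cf: CenteredFrame, n_pixels: int) -> np.ndarray:
    """Invert :func:`center_frame`: recover the original detector block
    (invalid pixels return as 0)."""
    occ = np.argwhere(cf.valid_mask)
    if occ.size == 0:
        raise ValueError("centered frame has no valid pixels")
    y0, x0 = occ.min(axis=0)
    # the occupied block is contiguous n×n minus any flagged pixels; clamp to
    # the canvas block origin by scanning from the top-left valid pixel
    y0 = max(int(y0), 0)
    x0 = max(int(x0), 0)
    return cf.pixels[y0 : y0 + n_pixels, x0 : x0 + n_pixels].copy()
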