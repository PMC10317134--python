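"""Detector and scan geometry for narrow-beam electron diffraction mapping.

The scattering geometry is fully determined by four quantities: the
accelerating voltage (which sets the relativistic electron wavelength), the
effective camera length, the detector pixel pitch and the detector size.
Within the small-angle regime that applies to sub-ångström wavelengths and
centimetre camera lengths, a lattice spacing ``d`` diffracts onto a ring of
radius ``r = λ·L / d`` on the detector, which this module converts to and
from pixel units.

Units at the interface follow common microscopy practice: kilovolts,
picometres, ångströms, micrometre pixel pitch, metre camera length and
nanometre scan steps.  Everything is converted to SI internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import yaml
from scipy import constants

__all__ = [
    "DetectorGeometry",
    "ScanGeometry",
    "electron_wavelength",
    "d_spacing_to_radius",
    "radius_to_d_spacing",
    "overlap_fraction",
    "canvas_size",
    "n_radial_bins",
    "load_geometry",
    "save_geometry",
]


@dataclass(frozen=True)
class DetectorGeometry:
    """Physical description of the diffraction camera.

    Parameters
    ----------
    pixel_pitch_um : float
        Pixel pitch in micrometres (hybrid pixel detectors are typically
        55 µm).
    n_pixels : int
        Detector side length in pixels; must be even (tiled detectors are).
    camera_length_m : float
        Effective (virtual) camera length in metres.
    accelerating_voltage_kv : float
        Accelerating voltage in kilovolts.
    """

    pixel_pitch_um: float = 55.0
    n_pixels: int = 512
    camera_length_m: float = 0.90
    accelerating_voltage_kv: float = 200.0

    def __post_init__(self) -> None:
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        if self.camera_length_m <= 0:
            raise ValueError("camera_length_m must be positive")
        if self.accelerating_voltage_kv <= 0:
            raise ValueError("accelerating_voltage_kv must be positive")
        if self.n_pixels <= 0 or self.n_pixels % 2 != 0:
            raise ValueError("n_pixels must be a positive even integer")

    @property
    def nominal_center(self) -> tuple[float, float]:
        """Geometric detector centre ``(x, y)`` with pixel centres at
        integer coordinates (so a 512-pixel side has its centre at 255.5)."""
        c = (self.n_pixels - 1) / 2.0
        return (c, c)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorGeometry":
        return cls(**d)


@dataclass(frozen=True)
class ScanGeometry:
    """Scan-grid layout: grid shape, step and beam footprint (nanometres)."""

    grid_shape: tuple[int, int] = (40, 40)
    step_nm: float = 30.0
    beam_diameter_nm: float = 60.0

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if rows < 1 or cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.step_nm <= 0:
            raise ValueError("step_nm must be positive")
        if self.beam_diameter_nm <= 0:
            raise ValueError("beam_diameter_nm must be positive")

    @property
    def n_points(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGeometry":
        d = dict(d)
        d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistically corrected de Broglie wavelength, in picometres.

    λ = h / sqrt(2 m₀ e V (1 + e V / 2 m₀ c²)); 200 kV gives 2.508 pm.
    """
    if voltage_kv <= 0:
        raise ValueError("accelerating voltage must be positive")
    v = voltage_kv * 1e3
    ev = constants.e * v
    p = math.sqrt(2 * constants.m_e * ev * (1 + ev / (2 * constants.m_e * constants.c**2)))
    return constants.h / p * 1e12


def d_spacing_to_radius(d_angstrom: float, geom: DetectorGeometry | None = None) -> float:
    """Detector radius (pixels, real-valued) of the ring for spacing ``d``.

    Small-angle mapping ``r = λ·L / d`` divided by the pixel pitch.  At the
    radii of interest here (≤ a few hundred pixels at 90 cm) the difference
    from the exact Bragg construction is far below one pixel.
    """
    if d_angstrom <= 0:
        raise ValueError("d-spacing must be positive")
    geom = geom or DetectorGeometry()
    lam_m = electron_wavelength(geom.accelerating_voltage_kv) * 1e-12
    r_m = lam_m * geom.camera_length_m / (d_angstrom * 1e-10)
    return r_m / (geom.pixel_pitch_um * 1e-6)


def radius_to_d_spacing(radius_px: float, geom: DetectorGeometry | None = None) -> float:
    """Inverse of :func:`d_spacing_to_radius` (ångströms)."""
    if radius_px <= 0:
        raise ValueError("radius must be positive")
    geom = geom or DetectorGeometry()
    lam_m = electron_wavelength(geom.accelerating_voltage_kv) * 1e-12
    d_m = lam_m * geom.camera_length_m / (radius_px * geom.pixel_pitch_um * 1e-6)
    return d_m * 1e10


def overlap_fraction(beam_diameter_nm: float, step_nm: float) -> float:
    """Fractional area overlap of two equal beam discs one scan step apart.

    Closed-form circular lens area divided by the disc area; 60 nm beam at a
    30 nm step gives ≈ 0.391.  Returns 0 for disjoint discs and 1 in the
    coincident limit.
    """
    if beam_diameter_nm <= 0 or step_nm <= 0:
        raise ValueError("beam diameter and step must be positive")
    r = beam_diameter_nm / 2.0
    d = step_nm
    if d >= 2 * r:
        return 0.0
    lens = 2 * r * r * math.acos(d / (2 * r)) - (d / 2.0) * math.sqrt(4 * r * r - d * d)
    return lens / (math.pi * r * r)


def canvas_size(n_pixels: int = 512) -> int:
    """Side length of the recentring canvas (1032 for a 512-pixel detector)."""
    return 2 * n_pixels + 8


def n_radial_bins(n_pixels: int = 512) -> int:
    """Number of 1-pixel radial bins spanning centre → canvas edge (516)."""
    return canvas_size(n_pixels) // 2


def save_geometry(path, geom: DetectorGeometry, scan: ScanGeometry | None = None) -> None:
    """Write geometry to a YAML key-value file (units are in the key names)."""
    doc: dict = {"detector": geom.to_dict()}
    if scan is not None:
        doc["scan"] = scan.to_dict()
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_geometry(path) -> tuple[DetectorGeometry, ScanGeometry | None]:
    """Read geometry written by :func:`save_geometry`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    geom = DetectorGeometry.from_dict(doc["detector"])
    scan = ScanGeometry.from_dict(doc["scan"]) if "scan" in doc else None
    return geom, scan
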