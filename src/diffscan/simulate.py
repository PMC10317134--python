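"""Synthetic narrow-beam diffraction scan simulator.

Generates 40×40 scan datasets with the statistical and geometric structure
that the downstream feature extraction and classifiers assume, so the whole
pipeline is testable without microscope data:

* a bright, narrow direct beam whose position drifts and jitters over the
  scan (no descan correction),
* an isotropic, radially decaying inelastic/low-angle background,
* class-specific diffuse rings — the 3.7 Å water ring of amorphous ice, two
  broad amorphous-carbon rings in the 2–4 Å range,
* discrete Bragg spots at hexagonal-ice spacings for crystalline ice,
* the tiling cross of a four-tile hybrid pixel detector,
* per-pixel Poisson counting noise and a multiplicative flat-field gain map,
* scan-grid region structure (ice regions in a carbon support, with blended
  "mixed" frames along region boundaries).

Expected-count templates are pure radial profiles (plus spots), so the
amorphous classes are isotropic by construction; all randomness flows
through explicit :class:`numpy.random.Generator` instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .geometry import DetectorGeometry, ScanGeometry, d_spacing_to_radius
from .labeling import ClassLabel, PURE_CLASSES, assign_labels, rasterize_roi

__all__ = [
    "FrameModel",
    "SceneSpec",
    "DiffractionFrame",
    "ScanDataset",
    "default_frame_models",
    "cross_mask",
    "class_template",
    "simulate_frame",
    "simulate_scan",
]


@dataclass(frozen=True)
class FrameModel:
    """Expected-count model of one pure class.

    Amplitudes are expected counts per pixel at the feature's peak; widths,
    decay lengths and spot sizes are in detector pixels; ring and spot
    positions are physical d-spacings in ångströms, converted to detector
    radii through the geometry at render time.
    """

    direct_beam: tuple[float, float] = (2000.0, 3.0)  # (peak amplitude, Gaussian sigma px)
    background: tuple[float, float] = (30.0, 45.0)  # (amplitude, radial decay length px)
    rings: tuple[tuple[float, float, float], ...] = ()  # (d Å, amplitude, sigma px)
    bragg_spots: tuple[int, int, tuple[float, ...], float, float] | None = None
    # (min spots, max spots, d-spacings Å, amplitude, sigma px)
    cross_half_width: int = 2
    cross_fill: float = 0.0
    jitter_sd: float = 1.0  # beam-centre jitter, px

    def __post_init__(self) -> None:
        if self.direct_beam[0] < 0 or self.background[0] < 0:
            raise ValueError("amplitudes must be non-negative")
        for d, amp, w in self.rings:
            if d <= 0:
                raise ValueError("ring d-spacings must be positive")
            if amp < 0 or w <= 0:
                raise ValueError("ring amplitude/width invalid")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.bragg_spots is not None:
            nmin, nmax, ds, amp, w = self.bragg_spots
            if not (1 <= nmin <= nmax):
                raise ValueError("spot count range invalid")
            if amp < 0 or w <= 0 or any(d <= 0 for d in ds):
                raise ValueError("bragg spot parameters invalid")


def default_frame_models(scale: float = 1.0) -> dict[ClassLabel, FrameModel]:
    """Default per-class frame models.

    Amorphous ice carries a narrow diffuse ring at the 3.7 Å water spacing
    (plus a weak second ring near 2.14 Å); amorphous carbon two broad rings
    at 3.5 and 2.1 Å realizing its characteristic 2–4 Å scattering;
    crystalline ice a weak diffuse ring plus 3–10 sharp Bragg spots on the
    hexagonal-ice spacings 3.90/3.67/3.44 Å at random azimuths.

    ``scale`` multiplies ring widths, background decay and spot width, for
    use with proportionally scaled detector geometries; physical d-spacings
    are untouched, and the direct-beam and spot widths never shrink below
    2 px (the detector point-spread floor — a feature narrower than that is
    not resolvable at any camera length).
    """
    s = scale
    beam_w = max(3.0 * s, 2.0)
    spot_w = max(3.0 * s, 2.0)
    return {
        ClassLabel.carbon: FrameModel(
            direct_beam=(2000.0, beam_w),
            background=(30.0, 45.0 * s),
            rings=((3.5, 6.0, 25.0 * s), (2.1, 3.0, 30.0 * s)),
        ),
        ClassLabel.amorphous_ice: FrameModel(
            direct_beam=(2000.0, beam_w),
            background=(30.0, 45.0 * s),
            rings=((3.7, 25.0, 5.0 * s), (2.14, 4.0, 10.0 * s)),
        ),
        ClassLabel.crystalline_ice: FrameModel(
            direct_beam=(2000.0, beam_w),
            background=(30.0, 45.0 * s),
            rings=((3.7, 10.0, 6.0 * s),),
            bragg_spots=(3, 10, (3.90, 3.67, 3.44), 150.0, spot_w),
        ),
    }


def cross_mask(n_pixels: int = 512, half_width: int = 2) -> np.ndarray:
    """Boolean mask of the detector tiling cross (True on cross pixels)."""
    m = np.zeros((n_pixels, n_pixels), dtype=bool)
    c = n_pixels // 2
    m[c - half_width : c + half_width, :] = True
    m[:, c - half_width : c + half_width] = True
    return m


def _radial_lut(model: FrameModel, geom: DetectorGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Isotropic expected-count profile sampled at 0.25 px steps."""
    r_max = np.sqrt(2.0) * geom.n_pixels + 2
    r = np.arange(0.0, r_max, 0.25)
    beam_amp, beam_w = model.direct_beam
    bg_amp, bg_decay = model.background
    prof = beam_amp * np.exp(-0.5 * (r / beam_w) ** 2) + bg_amp * np.exp(-r / bg_decay)
    for d, amp, w in model.rings:
        r0 = d_spacing_to_radius(d, geom)
        prof += amp * np.exp(-0.5 * ((r - r0) / w) ** 2)
    return r, prof


def draw_spot_set(model: FrameModel, rng: np.random.Generator) -> list[tuple[float, float]]:
    """Draw one crystal orientation: a list of (d-spacing, azimuth) pairs
    with a random spot count and random azimuths on the Bragg radii.  A
    contiguous crystal grain keeps one spot set across its scan points."""
    if model.bragg_spots is None:
        return []
    nmin, nmax, ds, _, _ = model.bragg_spots
    n_spots = int(rng.integers(nmin, nmax + 1))
    return [
        (ds[int(rng.integers(len(ds)))], float(rng.uniform(0, 2 * np.pi)))
        for _ in range(n_spots)
    ]


def _add_spots(
    img: np.ndarray,
    model: FrameModel,
    geom: DetectorGeometry,
    center: tuple[float, float],
    rng: np.random.Generator,
    weight: float = 1.0,
    spots: list[tuple[float, float]] | None = None,
) -> None:
    """Add Bragg spots (in place); ``spots`` fixes the orientation,
    otherwise a fresh random one is drawn."""
    if model.bragg_spots is None:
        return
    _, _, _, amp, w = model.bragg_spots
    n = geom.n_pixels
    half = max(int(np.ceil(4 * w)), 2)
    cx, cy = center
    if spots is None:
        spots = draw_spot_set(model, rng)
    for d, theta in spots:
        r0 = d_spacing_to_radius(d, geom)
        sx = cx + r0 * np.cos(theta)
        sy = cy + r0 * np.sin(theta)
        x0, x1 = int(np.floor(sx - half)), int(np.ceil(sx + half)) + 1
        y0, y1 = int(np.floor(sy - half)), int(np.ceil(sy + half)) + 1
        x0, x1 = max(x0, 0), min(x1, n)
        y0, y1 = max(y0, 0), min(y1, n)
        if x0 >= x1 or y0 >= y1:
            continue  # spot entirely off-detector
        yy, xx = np.mgrid[y0:y1, x0:x1]
        img[y0:y1, x0:x1] += (weight * amp) * np.exp(
            -0.5 * (((xx - sx) ** 2 + (yy - sy) ** 2) / w**2)
        )


def _expected_image(
    weights: dict[ClassLabel, float],
    model_set: dict[ClassLabel, FrameModel],
    geom: DetectorGeometry,
    center: tuple[float, float],
    rng: np.random.Generator | None,
    apply_cross: bool = True,
    spots: list[tuple[float, float]] | None = None,
) -> np.ndarray:
    n = geom.n_pixels
    cx, cy = center
    yy, xx = np.mgrid[0:n, 0:n]
    r = np.hypot(xx - cx, yy - cy)
    img = np.zeros((n, n), dtype=np.float64)
    any_model = None
    for label, w in weights.items():
        if w == 0:
            continue
        model = model_set[label]
        any_model = model
        lut_r, lut_v = _radial_lut(model, geom)
        img += w * np.interp(r, lut_r, lut_v)
        if model.bragg_spots is not None:
            if rng is None:
                rng = np.random.default_rng(0)
            _add_spots(img, model, geom, center, rng, weight=w, spots=spots)
    if apply_cross and any_model is not None:
        cm = cross_mask(n, any_model.cross_half_width)
        img[cm] = any_model.cross_fill
    return img


def class_template(
    label: ClassLabel,
    model: FrameModel,
    geom: DetectorGeometry | None = None,
    rng: np.random.Generator | None = None,
    apply_cross: bool = True,
) -> np.ndarray:
    """Noiseless expected-count image of one pure class at the nominal centre.

    Direct-beam peak + decaying isotropic background + diffuse class rings,
    plus azimuthally random Bragg spots for crystalline ice (``rng`` seeds
    the azimuths); cross pixels are overwritten with the fill value.
    """
    label = ClassLabel(label)
    if label == ClassLabel.mixed:
        raise ValueError("mixed is a blend, not a pure template; use simulate_frame")
    geom = geom or DetectorGeometry()
    return _expected_image({label: 1.0}, {label: model}, geom, geom.nominal_center, rng, apply_cross)


@dataclass
class DiffractionFrame:
    """One detector frame plus its scan-grid coordinate and true beam centre
    (``(x, y)``, sub-pixel, as placed by the simulator)."""

    pixels: np.ndarray
    scan_position: tuple[int, int]
    true_center: tuple[float, float]


def simulate_frame(
    label: ClassLabel,
    mix_weights: dict[ClassLabel, float] | None,
    model_set: dict[ClassLabel, FrameModel],
    geom: DetectorGeometry,
    center: tuple[float, float],
    rng: np.random.Generator,
    gain_map: np.ndarray | None = None,
    scan_position: tuple[int, int] = (0, 0),
    spots: list[tuple[float, float]] | None = None,
) -> DiffractionFrame:
    """Draw one noisy frame.

    Pixel counts are independent Poisson draws whose mean is the (possibly
    blended) expected-count template with the direct beam at ``center``,
    multiplied afterwards by the gain map (so flat-field correction is
    exactly invertible in expectation).  ``mix_weights`` must be a convex
    combination over pure classes and is required only for ``mixed``;
    ``spots`` fixes the crystal orientation (grains in one scan share one).
    """
    label = ClassLabel(label)
    if label == ClassLabel.mixed:
        if mix_weights is None:
            raise ValueError("mixed frames need mix_weights")
        w = {ClassLabel(k): float(v) for k, v in mix_weights.items()}
        if any(v < 0 for v in w.values()) or abs(sum(w.values()) - 1.0) > 1e-9:
            raise ValueError("mix_weights must be non-negative and sum to 1")
        if ClassLabel.mixed in w:
            raise ValueError("mix_weights must cover pure classes only")
    else:
        w = {label: 1.0}
    expected = _expected_image(w, model_set, geom, center, rng, spots=spots)
    counts = rng.poisson(expected).astype(np.float32)
    if gain_map is not None:
        counts *= gain_map.astype(np.float32, copy=False)
    return DiffractionFrame(pixels=counts, scan_position=scan_position, true_center=center)


@dataclass
class SceneSpec:
    """Region layout of one scan area.

    ``regions`` is a list of ``(ClassLabel, vertices)`` polygons in
    scan-grid coordinates (ice classes only); everything outside defaults to
    carbon, and labels within ``mixed_band`` (Chebyshev) of a class boundary
    become mixed.
    """

    grid_shape: tuple[int, int] = (40, 40)
    regions: list = field(default_factory=list)
    mixed_band: int = 1

    def to_dict(self) -> dict:
        return {
            "grid_shape": list(self.grid_shape),
            "regions": [
                {"label": ClassLabel(lbl).name, "vertices": np.asarray(v, float).tolist()}
                for lbl, v in self.regions
            ],
            "mixed_band": self.mixed_band,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        return cls(
            grid_shape=tuple(d["grid_shape"]),
            regions=[(ClassLabel[r["label"]], np.asarray(r["vertices"], float)) for r in d["regions"]],
            mixed_band=int(d["mixed_band"]),
        )


def demo_scene(grid_shape: tuple[int, int] = (40, 40), mixed_band: int = 1) -> SceneSpec:
    """A representative scene: one large amorphous-ice hole in carbon plus a
    smaller crystalline-ice contaminant, scaled to the grid."""
    rows, cols = grid_shape
    rs, cs = (rows - 1) / 39.0, (cols - 1) / 39.0
    hole = [(6 * cs, 8 * rs), (24 * cs, 5 * rs), (32 * cs, 18 * rs), (22 * cs, 33 * rs), (7 * cs, 28 * rs)]
    crystal = [(28 * cs, 26 * rs), (36 * cs, 27 * rs), (35 * cs, 36 * rs), (27 * cs, 34 * rs)]
    return SceneSpec(
        grid_shape=grid_shape,
        regions=[
            (ClassLabel.amorphous_ice, np.asarray(hole, float)),
            (ClassLabel.crystalline_ice, np.asarray(crystal, float)),
        ],
        mixed_band=mixed_band,
    )


@dataclass
class ScanDataset:
    """A full scan: one frame per grid point plus ground truth and metadata.

    ``frames`` is a (rows, cols, n, n) float32 array (Poisson counts times
    gain); ``true_centers[r, c]`` is the simulated beam centre ``(x, y)`` of
    that frame; ``labels`` the ground-truth class map.
    """

    frames: np.ndarray
    labels: np.ndarray
    true_centers: np.ndarray
    gain_map: np.ndarray
    invalid_mask: np.ndarray
    geometry: DetectorGeometry
    scan_geometry: ScanGeometry
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def n_frames(self) -> int:
        return self.labels.size

    def frame(self, row: int, col: int) -> DiffractionFrame:
        return DiffractionFrame(
            pixels=self.frames[row, col],
            scan_position=(row, col),
            true_center=tuple(self.true_centers[row, col]),
        )

    def flat_frames(self) -> np.ndarray:
        """(n_frames, n, n) view in row-major grid order."""
        r, c = self.grid_shape
        n = self.frames.shape[-1]
        return self.frames.reshape(r * c, n, n)


def _mixed_weights_map(scene: SceneSpec, scan_geom: ScanGeometry, supersample: int = 10):
    """Per-point convex blend weights from class area fractions within the
    beam disc, on a ``supersample``× raster of the scan grid."""
    rows, cols = scene.grid_shape
    ss = supersample
    # supersampled pure-class field (no mixed band) over the grid extent
    yy, xx = np.mgrid[0 : rows * ss, 0 : cols * ss]
    ys = yy / ss - 0.5 + 0.5 / ss
    xs = xx / ss - 0.5 + 0.5 / ss
    import shapely
    from shapely.geometry import Polygon

    field_lbl = np.full(ys.shape, int(ClassLabel.carbon), dtype=np.int8)
    order = [ClassLabel.amorphous_ice, ClassLabel.crystalline_ice]  # crystalline wins
    for want in order:
        for lbl, verts in scene.regions:
            if ClassLabel(lbl) != want:
                continue
            poly = Polygon(np.asarray(verts, float))
            pts = shapely.points(xs.ravel(), ys.ravel())
            inside = shapely.covers(poly, pts).reshape(ys.shape)
            field_lbl[inside] = int(want)
    beam_r = scan_geom.beam_diameter_nm / (2.0 * scan_geom.step_nm)  # scan units

    def weights_at(row: int, col: int) -> dict[ClassLabel, float]:
        d2 = (ys - row) ** 2 + (xs - col) ** 2
        disc = d2 <= beam_r**2
        vals = field_lbl[disc]
        if vals.size == 0:
            return {ClassLabel.carbon: 1.0}
        w = {}
        for c in PURE_CLASSES:
            frac = float(np.mean(vals == int(c)))
            if frac > 0:
                w[c] = frac
        total = sum(w.values())
        return {k: v / total for k, v in w.items()}

    return weights_at


def simulate_scan(
    scene: SceneSpec,
    model_set: dict[ClassLabel, FrameModel] | None = None,
    geom: DetectorGeometry | None = None,
    scan_geom: ScanGeometry | None = None,
    seed: int = 0,
    drift_px: tuple[float, float] = (6.0, 4.0),
    jitter_sd: float | None = None,
    gain_sd: float = 0.05,
) -> ScanDataset:
    """Simulate a full scan dataset.

    Labels come from the scene polygons through the labeling rules; each
    frame's beam centre is the nominal detector centre plus a linear drift
    ramp across the grid (``drift_px`` = (x, y) half-amplitudes, emulating
    uncorrected descan) plus i.i.d. Gaussian jitter; mixed points are
    blended with weights given by local class area fractions inside the beam
    footprint.  The flat-field gain map is 1 + N(0, gain_sd²) per pixel.
    Identical seed and scene give a bit-identical dataset.
    """
    geom = geom or DetectorGeometry()
    scan_geom = scan_geom or ScanGeometry(grid_shape=scene.grid_shape)
    if scan_geom.grid_shape != tuple(scene.grid_shape):
        raise ValueError("scene and scan geometry grid shapes differ")
    model_set = model_set or default_frame_models()
    rows, cols = scene.grid_shape
    n = geom.n_pixels

    ice = [rasterize_roi(v, scene.grid_shape) for l, v in scene.regions if ClassLabel(l) == ClassLabel.amorphous_ice]
    cry = [rasterize_roi(v, scene.grid_shape) for l, v in scene.regions if ClassLabel(l) == ClassLabel.crystalline_ice]
    labels = assign_labels(ice, cry, scene.mixed_band, scene.grid_shape)

    ss = np.random.SeedSequence(seed)
    gain_seed, grain_seed = ss.spawn(2)
    gain_rng = np.random.default_rng(gain_seed)
    frame_seeds = ss.spawn(rows * cols)
    gain_map = (1.0 + gain_sd * gain_rng.standard_normal((n, n))).clip(0.2).astype(np.float32)

    # one crystal orientation per scan: contiguous crystalline regions keep a
    # coherent Bragg-spot set, with a small per-frame azimuthal wobble
    cry_model = model_set.get(ClassLabel.crystalline_ice)
    base_spots = (
        draw_spot_set(cry_model, np.random.default_rng(grain_seed))
        if cry_model is not None and cry_model.bragg_spots is not None
        else []
    )

    any_model = next(iter(model_set.values()))
    inv_mask = cross_mask(n, any_model.cross_half_width)
    jsd = any_model.jitter_sd if jitter_sd is None else jitter_sd
    cx0, cy0 = geom.nominal_center
    weights_at = _mixed_weights_map(scene, scan_geom) if (labels == int(ClassLabel.mixed)).any() else None

    frames = np.empty((rows, cols, n, n), dtype=np.float32)
    centers = np.empty((rows, cols, 2), dtype=np.float64)
    mix_table: dict[tuple[int, int], dict[str, float]] = {}
    for r in range(rows):
        for c in range(cols):
            rng = np.random.default_rng(frame_seeds[r * cols + c])
            dx = drift_px[0] * (2.0 * c / max(cols - 1, 1) - 1.0)
            dy = drift_px[1] * (2.0 * r / max(rows - 1, 1) - 1.0)
            jx, jy = (rng.normal(0.0, jsd, 2) if jsd > 0 else (0.0, 0.0))
            center = (cx0 + dx + jx, cy0 + dy + jy)
            lbl = ClassLabel(int(labels[r, c]))
            mw = None
            if lbl == ClassLabel.mixed:
                mw = weights_at(r, c)
                mix_table[(r, c)] = {k.name: v for k, v in mw.items()}
            spots = None
            if base_spots and (lbl == ClassLabel.crystalline_ice
                               or (mw is not None and ClassLabel.crystalline_ice in mw)):
                spots = [(d, th + rng.normal(0.0, 0.03)) for d, th in base_spots]
            fr = simulate_frame(lbl, mw, model_set, geom, center, rng, gain_map, (r, c), spots=spots)
            frames[r, c] = fr.pixels
            centers[r, c] = center

    return ScanDataset(
        frames=frames,
        labels=labels,
        true_centers=centers,
        gain_map=gain_map,
        invalid_mask=inv_mask,
        geometry=geom,
        scan_geometry=scan_geom,
        seed=seed,
        metadata={
            "scene": scene.to_dict(),
            "drift_px": list(drift_px),
            "jitter_sd": jsd,
            "gain_sd": gain_sd,
            "mix_weights": {f"{r},{c}": w for (r, c), w in mix_table.items()},
        },
    )
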