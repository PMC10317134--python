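# diffscan

Classification of narrow-beam electron diffraction scans of holey-carbon
cryo-EM grids — with a synthetic scan simulator that makes the whole chain
testable without microscope data.

## The problem

A parallel electron beam of 50–60 nm is stepped in 30 nm increments over a
40×40 grid on a vitrified specimen; at every scan point a 512×512 hybrid
pixel detector records a far-field diffraction frame. Only some of those
frames are worth keeping: vitreous (amorphous) ice may contain the molecules
of interest, while carbon support film and crystalline-ice contamination do
not. At >1000 frames/s the data rate makes *post hoc* triage expensive, so
frames must be classified into {carbon, amorphous ice, crystalline ice,
mixed} from their scattering alone.

The physics that makes this possible:

- amorphous ice scatters into a diffuse ring at the water spacing
  d ≈ 3.7 Å — at 90 cm camera length and 200 kV that is a ring of radius
  r = λL/d ≈ 111 px;
- amorphous carbon scatters into broader rings spanning roughly 2–4 Å;
- crystalline ice adds discrete Bragg spots on hexagonal-ice spacings
  (3.90 / 3.67 / 3.44 Å);
- scan points whose 60 nm beam footprint straddles a region boundary (the
  ~39% overlap between neighbouring points guarantees such points exist)
  produce blended "mixed" patterns.

## What the package provides

| module | contents |
| --- | --- |
| `diffscan.geometry` | electron wavelength, d-spacing ↔ detector radius (r = λL/d), beam-overlap fraction, geometry configs |
| `diffscan.simulate` | synthetic scan generator: class templates, Poisson counting noise, flat-field gain, beam drift + jitter, detector tiling cross, polygon scenes with mixed boundary bands |
| `diffscan.labeling` | ROI-polygon rasterization → per-scan-point class maps with a Chebyshev mixed band |
| `diffscan.preprocess` | flat-field gain correction, sub-pixel beam-centre refinement, integer-shift recentring onto a 1032×1032 canvas |
| `diffscan.features` | RIA: 516-bin radial intensity averages; PCC: the 1600×1600 Pearson cross-correlation matrix of all frame pairs and its per-point slice maps |
| `diffscan.classify` | FCNN (one 30-unit hidden layer) and RBF-SVM on RIA profiles; a six-convolution-layer CNN on 150-px central crops; 90/10 stratified splits with whole held-out scans |
| `diffscan.evaluate` | confusion matrices, per-class and support-weighted precision/recall/F1/accuracy, difference maps |
| `diffscan.pipeline` / `diffscan.cli` | end-to-end driver and a thin `diffscan` command-line wrapper |

## Worked example

```python
import numpy as np
import diffscan as dsn
from diffscan.pipeline import extract_features

geom = dsn.DetectorGeometry()                  # 512 px, 55 µm, 90 cm, 200 kV
print(dsn.radius_to_d_spacing(150, geom))      # 2.7359  -> Å at 150 px
print(dsn.overlap_fraction(60, 30))            # 0.3910  -> 39% beam overlap

# simulate a scan (scaled detector for speed), refine centres, build features
geom_s = dsn.DetectorGeometry(n_pixels=128, camera_length_m=0.225)
models = dsn.default_frame_models(scale=0.25)
ds = dsn.simulate_scan(dsn.demo_scene((12, 12)), models, geom_s,
                       dsn.ScanGeometry(grid_shape=(12, 12)), seed=3)
ff = extract_features(ds, crop_radius=None)
err = np.hypot(*(ff.centers - ds.true_centers).transpose(2, 0, 1))
print(err.mean(), (err <= 1).mean())           # 0.569 px mean error, 100% ≤ 1 px
```

The printed numbers mean: 150 detector pixels reach 2.74 Å resolution,
neighbouring scan points share 39.1% of their area, and the beam-centre
refinement recovers the simulator's ground-truth centre to well under a
pixel for every frame — which is what keeps the sharp 3.7 Å water ring in
the same radial bin of every RIA profile despite the drifting beam.

The scripts in `examples/` walk through each capability one at a time
(geometry, simulation, centring + RIA, PCC maps, training + evaluation) and
print a short interpretation with every number.

## Limitations

The simulator reproduces the statistical structure of holey-carbon scan
data (ring positions, counting noise, beam drift, detector cross, region
blending), not the electron-optical physics; see `docs/methods.md` for the
model, its defaults, and what passing tests do and do not demonstrate about
real microscope data.
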