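# Methods

This note documents the models, defaults and design choices behind
`diffscan`, and what the synthetic tests do and do not establish about real
microscope data.

## Geometry

Scattering angles are small (a 3.7 Å ring at 200 kV subtends ~0.7 mrad), so
the detector radius of a lattice spacing `d` is taken as `r = λL/d` with the
relativistically corrected wavelength `λ = h/√(2m₀eV(1 + eV/2m₀c²))` and
camera length `L`. At the radii of interest the deviation from the exact
Bragg construction is far below one pixel. Defaults describe the instrument
class this pipeline targets: 512×512 pixels of 55 µm, `L` = 0.90 m,
200 kV. With those values 150 px ↔ 2.736 Å (quoted as 2.7 Å), and the
water ring of amorphous ice (3.7 Å) lands at 110.9 px. Note that 150 px ×
55 µm = 8.25 mm on the detector.

Beam overlap between neighbouring scan points is the closed-form circular
lens area for two discs of the beam diameter whose centres are one scan
step apart: 60 nm discs stepped 30 nm overlap by 39.1% — the reason
boundary scan points genuinely contain two materials and receive their own
"mixed" class.

Tests and examples frequently use a proportionally scaled geometry
(128-pixel detector at `L` = 0.225 m). Because `r ∝ L`, every ring keeps
its position relative to the detector edge, so all structural behaviour is
preserved at 1/16 of the pixel count; results quoted for the full geometry
are computed at the full geometry.

## Synthetic scan model

Each pure class is an isotropic expected-count template plus, for
crystalline ice, discrete Bragg spots:

- direct beam: Gaussian, peak 2000 counts, σ = 3 px;
- inelastic/low-angle background: 30·exp(−r/45 px);
- amorphous ice: rings at 3.7 Å (amplitude 25, σ 5 px) and 2.14 Å (4, 10);
- amorphous carbon: broad rings at 3.5 Å (6, 25) and 2.1 Å (3, 30),
  realizing its characteristic 2–4 Å scattering;
- crystalline ice: a weak diffuse ring at 3.7 Å (10, 6) plus 3–10 Gaussian
  spots (amplitude 150, σ 3 px) on the hexagonal-ice spacings
  3.90/3.67/3.44 Å. Spot azimuths are drawn once per scan — a contiguous
  crystal grain holds one orientation — with a ~1.7° per-frame wobble;
  fully independent azimuths would (unphysically) decorrelate the frames of
  one grain and destroy the within-region structure of the PCC matrix.

Ring amplitudes are not published anywhere; these defaults were chosen once
so that carbon and ice profiles are separable but overlapping at the given
counting statistics (total ≈ 5×10⁵ counts/frame, consistent with a
low-dose scan point on a counting detector). Noise is per-pixel Poisson on
the expected template — the dominant noise source of a hybrid pixel
counting detector — and the flat-field gain map (1 + N(0, 0.05²), clipped
positive) multiplies the counts *after* the draw, so gain correction divides
out exactly in expectation.

The detector tiling cross (a 4-pixel central horizontal + vertical band) is
overwritten with 0 and flagged invalid; all downstream statistics honour
that flag.

Scan structure: scene polygons (in scan-grid coordinates) select ice
regions; rasterization is a boundary-inclusive point-in-polygon test at the
scan-point centres; priority on overlap is crystalline > amorphous > carbon;
every point within Chebyshev distance `mixed_band` (default 1, ≈ one
beam-overlap zone) of a class boundary becomes mixed. Mixed frames are
blended with weights equal to each class's area fraction inside the beam
disc at that point, computed on a 10× supersampled raster. The beam centre
follows a linear drift ramp across the grid (default half-amplitudes
(6, 4) px, emulating uncorrected descan) plus i.i.d. N(0, 1 px²) jitter.
All randomness flows from named seeds through `numpy.random.SeedSequence`;
identical seed + scene gives a bit-identical dataset.

What the simulator does **not** model: atomic form factors and multislice
scattering, protein diffraction, ice-thickness gradients, detector
non-linearities beyond a static gain map, or beam-damage evolution. Passing
recovery tests therefore demonstrates that the pipeline's *mechanics* are
correct and robust to the modelled disturbances (drift, jitter, gain,
Poisson noise, session-amplitude changes) — not that the classifiers would
reach the same accuracy on real microscope sessions.

## Preprocessing

Flat-field correction divides by the gain map and refuses non-positive gain
values, naming the offending pixel.

Beam-centre refinement must cope with the tiling cross running right past
(sometimes through) the direct beam. Invalid pixels are first inpainted by
normalized Gaussian convolution (σ 3 px), the frame is median(3)- then
Gaussian(σ 2)-filtered, and the sub-pixel position comes from a weighted
least-squares paraboloid fit to the log intensity over the *originally
valid* pixels above 0.25·max in a 19-px window around the strongest
maximum. The log-paraboloid is exact for a Gaussian peak and stays unbiased
under one-sided masking, where a plain thresholded centroid is dragged by
up to ~1.5 px; measured on simulated frames the fit achieves ≈0.01 px bias,
≈0.33 px scatter, and 100% of frames within 1 px. On large frames the
filtering runs inside a 128-px box around a coarse block-mean argmax (the
beam dominates every other feature by an order of magnitude, so the coarse
stage cannot lock onto a spot); the full-frame path is available via a
parameter. A frame whose beam sits
entirely inside the dead cross is the one geometry where accuracy degrades;
with the default drift ramp this affects at most the few frames nearest the
grid centre. If the fit is degenerate (non-concave), the code falls back to
the intensity-weighted centroid.

Recentring moves the frame onto a canvas of side 2n+8 (1032 for n = 512)
by an **integer** shift — count data are moved, never resampled — with the
rounded centre landing on the canvas centre and the sub-pixel remainder
carried as a residual. Radial binning uses the sub-pixel centre (canvas
centre + residual) by default; a flag selects the integer centre instead.
Convention, used everywhere: 0-based indices, pixel centres at integer
coordinates, centres given as (x, y) = (column, row).

## Features

**RIA.** Every valid pixel is assigned to annulus `⌊r⌋` (half-open 1-px
annuli) by Euclidean distance to the centre; per-annulus means form a
516-value profile for the 1032-canvas. Annuli with no valid pixels (beyond
the frame corners) carry NaN; classifiers standardize per-feature on
training statistics and impute those NaNs as 0, keeping the feature length
fixed. The vectorized implementation is tested bit-for-bit against a
per-pixel loop.

**PCC.** Frames are variables, pixels observations: entry (i,j) is the
mean-centred covariance normalised by both standard deviations — the only
reading that yields a 1600×1600 matrix for 1600 frames. Cross pixels are
excluded via the common valid mask; constant frames get a NaN row/column
rather than an error. The Gram product runs in the input dtype, so large
stacks can be correlated in float32; the small-matrix path is verified to
1e-12 against a two-loop evaluation.

## Classifiers

All three classifiers are deterministic given their seed, expose per-class
scores summing to 1, and serialize/reload with bit-identical predictions.
Standardization statistics always come from training data only and are
stored with the model.

- **FCNN**: one hidden layer of 30 tanh units, softmax output, categorical
  cross-entropy, trained with Adam (the loss is the contract; the optimizer
  is configuration), scikit-learn `MLPClassifier` underneath.
- **SVM**: RBF kernel, C = 1, γ = 1/n_features. On profiles the bundled
  scaler has already standardized, γ = 1/d is the appropriate scale-free
  width; variance-rescaled heuristics overestimate γ here because ~30% of
  the 516 bins are constant zero-imputed outer annuli, and the resulting
  narrow kernel memorizes session intensity levels (measured: ~61% vs 100%
  pure-class accuracy on a perturbed held-out session). A randomized search
  (log-uniform C ∈ [0.1, 10³], γ ∈ [10⁻⁴, 1], 20 draws) is available but
  the defaults are already competitive.
- **CNN**: six 3×3 convolutions (8,8,16,16,32,32 channels), 2×2 max-pool +
  dropout 0.25 after every second convolution, a 64-unit dense layer,
  softmax; Adam, minibatch 32, early stopping on validation loss with best
  weights restored. The input is the 301×301 central crop (150-px radius ↔
  2.7 Å), circularly masked, log1p-transformed, block-mean downsampled 6×
  to 50×50 so CPU training stays at desk scale. Training applies a random
  dihedral transform (90° rotations and flips) to every crop each epoch:
  the crops are centred and their class content is rotation-covariant
  (rings isotropic, spot azimuths arbitrary), so the label is invariant —
  without it the network memorizes the few grain orientations present in a
  small training pool and misreads unseen orientations. The exact widths
  are configuration, not contract. Implemented as a compact self-contained
  NumPy network (im2col convolutions); gradient flow and determinism are
  unit-tested.

**Split protocol.** Named scans held out for testing are never touched by
training or tuning; the remaining scans are pooled and split 90/10 at frame
level, stratified by class. Recovery experiments train on **six** simulated
sessions, each with its own ±10% ring/background amplitude draw and drift
ramp, and test on a seventh: with a single training session every
classifier latches onto session-specific intensity levels (pure-class
accuracy drops into the 80s), and a controlled comparison on fixed held-out
sessions put the FCNN at 0.76–0.99 pure-class accuracy with three training
sessions versus 0.92–0.98 with six. Pooling sessions — the synthetic
analogue of training on 15 scans — is what teaches amplitude invariance;
the FCNN remains the most session-sensitive of the three classifiers, as
it was on the real data. The CNN trains on crops from three of the
sessions; its dihedral augmentation already supplies the orientation
diversity it needs.

## Evaluation

Confusion matrices have actual classes in rows, predictions in columns,
fixed class order (carbon, amorphous ice, crystalline ice, mixed).
Precision = TP/(TP+FP) with FP the column sum minus TP; recall = TP/(TP+FN)
with FN the row sum minus TP; F1 their harmonic mean; accuracy the trace
over the total. Weighted averages use actual-class supports, which makes
weighted recall *identically* equal to accuracy
(Σᵢ(nᵢ/N)(TPᵢ/nᵢ) = trace/N); the suite checks the identity to 1e-12 on
random matrices. Zero-denominator metrics are reported as NaN and enter the
weighted averages only through their (zero) support.

## Problem sizes

Unit and property tests run the scaled 128-px geometry on 12–24-point
grids. The acceptance workflow runs the full 512-px geometry: 20×20 grids
for the seven sessions of the recovery experiment (2800 frames end to
end), a 40×40 scan for the PCC contract, 400 frames for beam-centre
recovery, and 400 frames for the crop-resolution mechanism check. These sizes were
chosen as the package's own desk-scale defaults; every quantity is
recomputed from scratch at run time.

## Known limitations

- The mixed band labels some points whose beam footprint barely (or not at
  all) reaches the second material; such frames are physically pure, so a
  residual pure↔mixed confusion is inherent to the labelling scheme — on
  synthetic data exactly as reported for the real experiment, the majority
  of errors sit on mixed-band points.
- The beam-centre fit degrades when the beam centre falls entirely inside
  the dead tiling cross.
- `find_beam_center` assumes the direct beam is the brightest feature after
  smoothing; a Bragg spot brighter than the beam would be mistaken for it.
- The CNN cannot, by construction, see Bragg spots beyond its 150-px crop;
  crystalline ice whose spots all lie outside is indistinguishable from
  amorphous ice for it (this is verified, not worked around).
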