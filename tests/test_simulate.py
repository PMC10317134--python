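"""Synthetic scan simulator: templates, noise statistics, scene structure."""

import numpy as np
import pytest

import diffscan as dsn
from diffscan.geometry import d_spacing_to_radius
from diffscan.labeling import ClassLabel, assign_labels, rasterize_roi
from diffscan.simulate import class_template, cross_mask, simulate_frame, simulate_scan

from conftest import make_centered


def template_ria(img, geom, invalid=None):
    """RIA of a template about the exact nominal centre (features module)."""
    cf = dsn.center_frame(img, geom.nominal_center, invalid_mask=invalid)
    return dsn.radial_average(cf).values


class TestClassTemplate:
    def test_ice_ring_at_water_spacing(self, small_geom, small_models):
        # the strongest background-subtracted RIA feature away from the beam
        # must sit at the 3.7 A ring radius
        ice = small_models[ClassLabel.amorphous_ice]
        bg_only = dsn.FrameModel(direct_beam=ice.direct_beam, background=ice.background)
        cm = cross_mask(small_geom.n_pixels, ice.cross_half_width)
        t_ice = class_template(ClassLabel.amorphous_ice, ice, small_geom)
        t_bg = class_template(ClassLabel.carbon, bg_only, small_geom)
        ria = template_ria(t_ice - t_bg, small_geom, invalid=cm)
        r_lo, r_hi = 15, 50  # scaled analogue of the 60..200 px search band
        peak_bin = r_lo + np.nanargmax(ria[r_lo:r_hi])
        r_expected = d_spacing_to_radius(3.7, small_geom)
        assert abs(peak_bin - r_expected) <= 2

    def test_zero_amplitudes_give_zero_image(self, small_geom):
        model = dsn.FrameModel(direct_beam=(0.0, 3.0), background=(0.0, 45.0))
        t = class_template(ClassLabel.carbon, model, small_geom)
        assert t.shape == (128, 128)
        assert np.all(t == 0)

    def test_carbon_and_ice_differ_strongly(self, small_geom, small_models):
        cm = cross_mask(small_geom.n_pixels)
        t_c = template_ria(class_template(ClassLabel.carbon, small_models[ClassLabel.carbon], small_geom), small_geom, cm)
        t_i = template_ria(class_template(ClassLabel.amorphous_ice, small_models[ClassLabel.amorphous_ice], small_geom), small_geom, cm)
        bg_amp, bg_decay = small_models[ClassLabel.carbon].background
        r = np.arange(len(t_c), dtype=float)
        bg = bg_amp * np.exp(-r / bg_decay)
        diff = np.abs(np.nan_to_num(t_c - t_i))
        assert (diff > 5 * bg).any()

    def test_mixed_label_rejected(self, small_geom, small_models):
        with pytest.raises(ValueError):
            class_template(ClassLabel.mixed, small_models[ClassLabel.carbon], small_geom)

    def test_amorphous_isotropy(self, full_geom):
        # azimuthal coefficient of variation on fixed-radius annuli < 2%
        # (full-size geometry: annulus discretization is negligible there)
        models = dsn.default_frame_models()
        t = class_template(ClassLabel.amorphous_ice, models[ClassLabel.amorphous_ice],
                           full_geom, apply_cross=False)
        n = full_geom.n_pixels
        cx, cy = full_geom.nominal_center
        yy, xx = np.mgrid[0:n, 0:n]
        r = np.hypot(xx - cx, yy - cy)
        for radius in (30, 110.9, 160):  # background, water ring, far background
            ring = np.abs(r - radius) < 0.5
            vals = t[ring]
            assert vals.std() / vals.mean() < 0.02

    def test_crystalline_anisotropy(self, small_geom, small_models):
        t = class_template(ClassLabel.crystalline_ice, small_models[ClassLabel.crystalline_ice],
                           small_geom, rng=np.random.default_rng(0), apply_cross=False)
        n = small_geom.n_pixels
        cx, cy = small_geom.nominal_center
        yy, xx = np.mgrid[0:n, 0:n]
        r = np.hypot(xx - cx, yy - cy)
        ratios = []
        for d in (3.90, 3.67, 3.44):
            radius = d_spacing_to_radius(d, small_geom)
            ring = np.abs(r - radius) < 1.0
            ratios.append(t[ring].max() / t[ring].mean())
        assert max(ratios) > 5


class TestSimulateFrame:
    def test_infinite_dose_limit(self, small_geom, small_models):
        # scaling the expected counts up makes the relative noise vanish
        label = ClassLabel.amorphous_ice
        boosted = {
            label: dsn.FrameModel(
                direct_beam=(small_models[label].direct_beam[0] * 1e6, small_models[label].direct_beam[1]),
                background=(small_models[label].background[0] * 1e6, small_models[label].background[1]),
                rings=tuple((d, a * 1e6, w) for d, a, w in small_models[label].rings),
            )
        }
        rng = np.random.default_rng(0)
        center = small_geom.nominal_center
        fr = simulate_frame(label, None, boosted, small_geom, center, rng)
        template = class_template(label, boosted[label], small_geom)
        ok = template > 0
        rms = np.sqrt(np.mean(((fr.pixels[ok] - template[ok]) / template[ok]) ** 2))
        assert rms < 0.005

    def test_seed_reproducibility(self, small_geom, small_models):
        center = (60.0, 70.0)
        f1 = simulate_frame(ClassLabel.crystalline_ice, None, small_models, small_geom,
                            center, np.random.default_rng(123))
        f2 = simulate_frame(ClassLabel.crystalline_ice, None, small_models, small_geom,
                            center, np.random.default_rng(123))
        np.testing.assert_array_equal(f1.pixels, f2.pixels)

    def test_poisson_mean_recovery(self, small_geom, small_models):
        # per-pixel sample mean over many frames within 3 SE of the template
        label = ClassLabel.carbon
        template = class_template(label, small_models[label], small_geom)
        n_rep = 300
        rng = np.random.default_rng(9)
        acc = np.zeros_like(template)
        for _ in range(n_rep):
            acc += simulate_frame(label, None, small_models, small_geom,
                                  small_geom.nominal_center, rng).pixels
        mean = acc / n_rep
        se = np.sqrt(np.maximum(template, 1e-12) / n_rep)
        ok = template > 0.5  # skip near-zero pixels where SE ~ 0
        frac = np.mean(np.abs(mean[ok] - template[ok]) <= 3 * se[ok])
        assert frac >= 0.99

    def test_poisson_dispersion(self, small_geom, small_models):
        # variance/mean of counts over repeated draws stays near 1 (pre-gain)
        label = ClassLabel.amorphous_ice
        rng = np.random.default_rng(4)
        draws = np.stack([
            simulate_frame(label, None, small_models, small_geom,
                           small_geom.nominal_center, rng).pixels
            for _ in range(1000)
        ])
        sel = np.s_[43:47, 43:47]  # on the ice ring, away from the cross
        m = draws[:, sel[0], sel[1]].mean(axis=0)
        v = draws[:, sel[0], sel[1]].var(axis=0)
        idx = v / m
        assert np.all((idx > 0.9) & (idx < 1.1))

    def test_mix_weights_validation(self, small_geom, small_models):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            simulate_frame(ClassLabel.mixed, None, small_models, small_geom, (64, 64), rng)
        with pytest.raises(ValueError):
            simulate_frame(ClassLabel.mixed, {ClassLabel.carbon: 0.7}, small_models,
                           small_geom, (64, 64), rng)
        with pytest.raises(ValueError):
            simulate_frame(ClassLabel.mixed, {ClassLabel.carbon: 1.5, ClassLabel.amorphous_ice: -0.5},
                           small_models, small_geom, (64, 64), rng)


class TestSimulateScan:
    def test_full_ice_scene_labels(self, small_models, small_geom):
        scene = dsn.SceneSpec(grid_shape=(6, 6),
                              regions=[(ClassLabel.amorphous_ice, [(-1, -1), (6, -1), (6, 6), (-1, 6)])],
                              mixed_band=0)
        ds = simulate_scan(scene, small_models, small_geom,
                           dsn.ScanGeometry(grid_shape=(6, 6)), seed=0)
        assert (ds.labels == int(ClassLabel.amorphous_ice)).all()

    def test_labels_match_labeling_module(self, small_scan, two_region_scene):
        ice = [rasterize_roi(v, (16, 16)) for l, v in two_region_scene.regions
               if l == ClassLabel.amorphous_ice]
        cry = [rasterize_roi(v, (16, 16)) for l, v in two_region_scene.regions
               if l == ClassLabel.crystalline_ice]
        expected = assign_labels(ice, cry, two_region_scene.mixed_band, (16, 16))
        np.testing.assert_array_equal(small_scan.labels, expected)

    def test_zero_jitter_zero_drift_centers(self, small_models, small_geom):
        scene = dsn.SceneSpec(grid_shape=(3, 3), regions=[], mixed_band=0)
        ds = simulate_scan(scene, small_models, small_geom,
                           dsn.ScanGeometry(grid_shape=(3, 3)), seed=1,
                           drift_px=(0.0, 0.0), jitter_sd=0.0)
        expected = np.broadcast_to(np.asarray(small_geom.nominal_center), (3, 3, 2))
        np.testing.assert_allclose(ds.true_centers, expected)

    def test_bit_identical_reproducibility(self, two_region_scene, small_models, small_geom):
        kw = dict(scene=two_region_scene, model_set=small_models, geom=small_geom,
                  scan_geom=dsn.ScanGeometry(grid_shape=(16, 16)), seed=42,
                  drift_px=(1.5, -1.0))
        d1 = simulate_scan(**kw)
        d2 = simulate_scan(**kw)
        np.testing.assert_array_equal(d1.frames, d2.frames)
        np.testing.assert_array_equal(d1.gain_map, d2.gain_map)
        np.testing.assert_array_equal(d1.true_centers, d2.true_centers)

    def test_one_frame_per_point_and_metadata(self, small_scan):
        assert small_scan.frames.shape == (16, 16, 128, 128)
        assert small_scan.labels.shape == (16, 16)
        assert small_scan.n_frames == 256
        assert (small_scan.frames >= 0).all()
        assert small_scan.metadata["scene"]["grid_shape"] == [16, 16]

    def test_mixed_frames_have_blend_weights(self, small_scan):
        mixed = np.argwhere(small_scan.labels == int(ClassLabel.mixed))
        assert len(mixed) > 0
        w = small_scan.metadata["mix_weights"]
        for r, c in mixed:
            assert f"{r},{c}" in w
            vals = list(w[f"{r},{c}"].values())
            assert all(v >= 0 for v in vals)
            assert sum(vals) == pytest.approx(1.0)
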