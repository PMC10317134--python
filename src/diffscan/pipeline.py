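"""End-to-end pipeline: simulate → preprocess → features → train → evaluate.

A :class:`PipelineConfig` plus its seeds reproduces a run bit-identically
through preprocessing and deterministically through training.  Held-out
"sessions" are simulated with a fresh seed, a different beam-centre drift
ramp and ring amplitudes perturbed by ±10%, emulating a scan recorded at a
different time with similar but not identical alignment.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .classify import (
    CNNConfig,
    FCNNConfig,
    SplitSpec,
    SVMConfig,
    crop_central,
    predict_map,
    split_datasets,
    train_cnn,
    train_fcnn,
    train_svm,
)
from .evaluate import confusion, difference_map, metrics
from .features import radial_average
from .geometry import DetectorGeometry, ScanGeometry, n_radial_bins
from .labeling import ClassLabel
from .preprocess import center_frame, find_beam_center, gain_correct
from .simulate import FrameModel, ScanDataset, default_frame_models, demo_scene, simulate_scan
from .storage import write_centers_table, write_dataset, write_ria_csv

__all__ = [
    "PipelineConfig",
    "FrameFeatures",
    "extract_features",
    "perturb_models",
    "run_pipeline",
]

log = logging.getLogger("diffscan")


@dataclass
class PipelineConfig:
    """Everything a full run needs; serializable to YAML."""

    n_pixels: int = 512
    camera_length_m: float = 0.90
    grid_shape: tuple[int, int] = (40, 40)
    n_train_scans: int = 2
    mixed_band: int = 1
    seed: int = 0
    crop_radius: int = 150
    downsample: int = 6
    model_scale: float = 1.0
    amp_perturbation: float = 0.10
    split: SplitSpec = field(default_factory=SplitSpec)
    fcnn: FCNNConfig = field(default_factory=FCNNConfig)
    svm: SVMConfig = field(default_factory=SVMConfig)
    cnn: CNNConfig = field(default_factory=CNNConfig)

    def detector(self) -> DetectorGeometry:
        return DetectorGeometry(n_pixels=self.n_pixels, camera_length_m=self.camera_length_m)

    def scan(self) -> ScanGeometry:
        return ScanGeometry(grid_shape=self.grid_shape)

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["grid_shape"] = list(self.grid_shape)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        doc["grid_shape"] = tuple(doc["grid_shape"])
        for key, typ in (("split", SplitSpec), ("fcnn", FCNNConfig), ("svm", SVMConfig), ("cnn", CNNConfig)):
            if key in doc and isinstance(doc[key], dict):
                d = doc[key]
                for k in ("test_ids", "channels"):
                    if k in d and isinstance(d[k], list):
                        d[k] = tuple(d[k])
                doc[key] = typ(**d)
        return cls(**doc)

    def digest(self) -> str:
        doc = asdict(self)
        doc["grid_shape"] = list(self.grid_shape)
        return hashlib.sha256(json.dumps(doc, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class FrameFeatures:
    """Per-scan feature bundle: refined centres and residuals (grid-shaped),
    RIA profiles and CNN crops (flat, row-major grid order)."""

    centers: np.ndarray
    residuals: np.ndarray
    profiles: np.ndarray
    crops: np.ndarray | None


def extract_features(
    ds: ScanDataset,
    crop_radius: int | None = 150,
    downsample: int = 6,
    use_subpixel_center: bool = True,
    center_override: np.ndarray | None = None,
) -> FrameFeatures:
    """Gain-correct, centre-refine, recentre and featurize every frame.

    ``center_override`` (grid, 2) substitutes fixed centres for the refined
    ones — useful to measure what an uncorrected beam drift costs.
    """
    rows, cols = ds.grid_shape
    nb = n_radial_bins(ds.geometry.n_pixels)
    centers = np.empty((rows, cols, 2))
    residuals = np.empty((rows, cols, 2))
    profiles = np.empty((rows * cols, nb))
    crops = None
    for r in range(rows):
        for c in range(cols):
            corrected = gain_correct(ds.frames[r, c], ds.gain_map)
            if center_override is None:
                bc = find_beam_center(corrected, invalid_mask=ds.invalid_mask)
                center = (bc.x, bc.y)
            else:
                center = tuple(center_override[r, c])
            cf = center_frame(corrected, center, invalid_mask=ds.invalid_mask)
            centers[r, c] = center
            residuals[r, c] = cf.residual
            profiles[r * cols + c] = radial_average(
                cf, n_bins=nb, use_subpixel_center=use_subpixel_center
            ).values
            if crop_radius is not None:
                crop = crop_central(cf, radius=crop_radius, downsample=downsample)
                if crops is None:
                    crops = np.empty((rows * cols, *crop.shape), dtype=np.float32)
                crops[r * cols + c] = crop
    return FrameFeatures(centers=centers, residuals=residuals, profiles=profiles, crops=crops)


def perturb_models(
    model_set: dict, rng: np.random.Generator, amp_frac: float = 0.10
) -> dict:
    """Ring-amplitude perturbation (±``amp_frac``, uniform) applied
    per class — the synthetic analogue of a session with similar but not
    identical alignment and illumination."""
    out = {}
    for label, m in model_set.items():
        rings = tuple(
            (d, amp * (1 + rng.uniform(-amp_frac, amp_frac)), w) for d, amp, w in m.rings
        )
        spots = m.bragg_spots
        if spots is not None:
            nmin, nmax, ds_, amp, w = spots
            spots = (nmin, nmax, ds_, amp * (1 + rng.uniform(-amp_frac, amp_frac)), w)
        out[label] = FrameModel(
            direct_beam=m.direct_beam,
            background=(m.background[0] * (1 + rng.uniform(-amp_frac, amp_frac)), m.background[1]),
            rings=rings,
            bragg_spots=spots,
            cross_half_width=m.cross_half_width,
            cross_fill=m.cross_fill,
            jitter_sd=m.jitter_sd,
        )
    return out


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the whole chain and write datasets, features, models and reports
    into ``out_dir``; returns the report dictionary.

    Stages: simulate ``n_train_scans`` training scans plus one held-out
    session (new seed, new drift ramp, perturbed amplitudes) → preprocess and
    featurize → train FCNN, SVM and CNN → predict the held-out session →
    confusion matrices and metric reports.  Each stage logs one line with its
    input/output counts; every output embeds the config digest and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geom, scan_geom = config.detector(), config.scan()
    scale = config.model_scale if config.model_scale != 1.0 else geom.n_pixels / 512
    models = default_frame_models(scale=scale)
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(config.n_train_scans + 2)]

    datasets: dict[str, ScanDataset] = {}
    stage = "simulate"
    try:
        for i in range(config.n_train_scans):
            scene = demo_scene(config.grid_shape, config.mixed_band)
            datasets[f"train{i}"] = simulate_scan(scene, models, geom, scan_geom, seed=seeds[i])
        held_rng = np.random.default_rng(seeds[-1])
        held_models = perturb_models(models, held_rng, config.amp_perturbation)
        datasets["heldout"] = simulate_scan(
            demo_scene(config.grid_shape, config.mixed_band),
            held_models, geom, scan_geom, seed=seeds[-2],
            drift_px=(-5.0, 7.0),
        )
        log.info("simulate: %d scans × %d frames", len(datasets), scan_geom.n_points)

        stage = "preprocess/features"
        feats: dict[str, FrameFeatures] = {}
        for name, ds in datasets.items():
            feats[name] = extract_features(ds, config.crop_radius, config.downsample)
            write_dataset(out / f"{name}.h5", ds)
            write_ria_csv(out / f"{name}_ria.csv", feats[name].profiles, ds.labels)
            write_centers_table(out / f"{name}_centers.txt", feats[name].centers, feats[name].residuals)
        nb = feats["heldout"].profiles.shape[1]
        log.info("features: %d frames → %d RIA bins, crops %s",
                 sum(d.n_frames for d in datasets.values()), nb,
                 feats["heldout"].crops.shape[1:])

        stage = "train"
        split = SplitSpec(config.split.train_fraction, ("heldout",), config.split.seed)
        ria_sets = {k: (feats[k].profiles, datasets[k].labels) for k in datasets}
        (X_tr, y_tr), (X_val, y_val), _ = split_datasets(ria_sets, split)
        fcnn = train_fcnn(X_tr, y_tr, config.fcnn)
        svm = train_svm(X_tr, y_tr, config.svm)
        crop_sets = {k: (feats[k].crops, datasets[k].labels) for k in datasets}
        (C_tr, cy_tr), (C_val, cy_val), _ = split_datasets(crop_sets, split)
        cnn = train_cnn(C_tr, cy_tr, config.cnn, C_val, cy_val)
        fcnn.save(out / "fcnn.joblib")
        svm.save(out / "svm.joblib")
        cnn.save(out / "cnn.joblib")
        log.info("train: fcnn/svm on %d profiles (+%d val), cnn on %d crops", len(X_tr), len(X_val), len(C_tr))

        stage = "evaluate"
        held = datasets["heldout"]
        report = {
            "config_digest": config.digest(),
            "seed": config.seed,
            "versions": {"diffscan": __version__, "numpy": np.__version__},
            "models": {},
        }
        for name, clf, features in (
            ("fcnn", fcnn, feats["heldout"].profiles),
            ("svm", svm, feats["heldout"].profiles),
            ("cnn", cnn, feats["heldout"].crops),
        ):
            pred, _ = predict_map(clf, features, held.grid_shape)
            cm = confusion(held.labels, pred)
            rep = metrics(cm)
            diff, per_class = difference_map(held.labels, pred)
            report["models"][name] = {
                "confusion": cm.counts.tolist(),
                "metrics": rep.to_dict(),
                "errors_by_actual_class": per_class,
                "n_misclassified": int(diff.sum()),
            }
            np.savetxt(out / f"{name}_predicted.csv", pred, fmt="%d", delimiter=",")
            log.info("evaluate %s: accuracy %.3f, weighted F1 %.3f", name, rep.accuracy, rep.weighted_f1)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1)
        return report
    except Exception as err:  # pragma: no cover - error path
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err
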