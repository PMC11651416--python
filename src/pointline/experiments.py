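"""Reference experiments on synthetic scenes.

``run_end_to_end`` is the package's standard desk-scale exercise: generate a
few hundred small early/middle-stage scenes, preprocess them into detection
samples, train the tiny backbone profile briefly, and evaluate detection mAP
and trajectory mLD on a held-out split — including the hard-NMS versus
D-IoU-Soft-NMS comparison at the box-suppression stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotations import CATEGORIES
from .detmetrics import evaluate_detections
from .geometry import Box, match_detections, mean_line_distance
from .network import (
    ModelConfig,
    TrainConfig,
    TrainingSample,
    build_model,
    prepare_sample,
    train,
)
from .postprocess import NMSConfig, detections_to_predictions
from .synthdata import SceneConfig, generate_scene


@dataclass
class _GroundTruth:
    category: str
    points: np.ndarray


def make_samples(
    n_scenes: int,
    seed: int,
    image_size: int = 256,
    stages: tuple[str, ...] = ("early", "middle"),
) -> list[TrainingSample]:
    """Generate and preprocess scenes, cycling through the given stage presets."""
    rng = np.random.default_rng(seed)
    scene_seeds = rng.integers(0, 2**31 - 1, size=n_scenes)
    samples = []
    for i, s in enumerate(scene_seeds):
        stage = stages[i % len(stages)]
        cfg = SceneConfig.for_stage(stage, seed=int(s), image_size=(image_size, image_size))
        image, ann = generate_scene(cfg)
        samples.append(prepare_sample(image, ann))
    return samples


def _gts_for(sample: TrainingSample) -> list[tuple[Box, _GroundTruth]]:
    return [
        (Box(*b), _GroundTruth(CATEGORIES[l - 1], k))
        for b, l, k in zip(sample.boxes, sample.labels, sample.keypoints)
    ]


def evaluate_split(
    model, samples, nms: NMSConfig
) -> dict:
    """mAP50/mAP75 and mLD of a trained model on prepared samples."""
    dets_by, gts_by = {}, {}
    lds: list[float] = []
    for i, s in enumerate(samples):
        raw = model.predict_raw(s.image)
        dets = detections_to_predictions(raw, nms)
        gts = _gts_for(s)
        dets_by[i], gts_by[i] = dets, gts
        table = match_detections(dets, gts, 0.5)
        lds.extend(mean_line_distance(table, dets, gts).per_target_ld)
    report = evaluate_detections(dets_by, gts_by, (0.5, 0.75))
    return {
        "map50": report.map_per_threshold[0.5],
        "map75": report.map_per_threshold[0.75],
        "mld": float(np.mean(lds)) if lds else None,
        "n_matched": len(lds),
    }


def run_end_to_end(
    seed: int = 0,
    n_scenes: int = 200,
    image_size: int = 256,
    epochs: int = 10,
    n_val: int = 20,
    n_test: int = 20,
) -> dict:
    """Full pipeline at desk scale; returns metrics on the held-out test split.

    The training recipe for the tiny profile is SGD with base lr 0.01 stepped
    by 0.66 every 4 epochs — the full-scale schedule shape at a learning rate
    suited to the small from-scratch trunk.
    """
    ss = np.random.SeedSequence(seed)
    data_seed, train_seed = (int(s) % (2**31 - 1) for s in ss.generate_state(2))
    samples = make_samples(n_scenes, data_seed, image_size)
    n_train = n_scenes - n_val - n_test
    tr = samples[:n_train]
    va = samples[n_train : n_train + n_val]
    te = samples[n_train + n_val :]

    model = build_model(ModelConfig.tiny_profile(seed=train_seed))
    tcfg = TrainConfig(
        epochs=epochs, base_lr=0.01, lr_step=4, lr_gamma=0.66, seed=train_seed
    )
    history = train(model, tr, tcfg, val_samples=va, eval_every=2)

    result = {
        "n_train": n_train,
        "n_test": len(te),
        "epochs": epochs,
        "best_val_map50": history["best_val_map50"],
        "first_val_map50": next(
            (v for v in history["val_map50"] if v is not None), None
        ),
    }
    result["soft_diou"] = evaluate_split(model, te, NMSConfig(mode="soft_diou"))
    result["hard"] = evaluate_split(model, te, NMSConfig(mode="hard"))
    return result
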