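"""End-to-end workflow: preprocess, dehair, train, weight, fuse, report.

``run_pipeline`` consumes a dataset manifest (path, label, split), trains
the native classifiers on the learning split, measures every classifier's
validation accuracy (which become the fusion weights), fuses hard votes on
the testing split, and writes one JSON report carrying a performance
report per classifier plus the fused ensemble, together with the config
snapshot.  Config snapshot + seed fully determine the report.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .classifiers import (
    ClassifierModel,
    predict,
    register_external_classifier,
    train_hog_svm,
    train_mlp_on_images,
)
from .config import DEFAULT_CONFIG, load_config
from .fusion import FusionEnsemble, fuse, weights_from_validation
from .hairremoval import HairRemovalParams, remove_hair
from .metrics import confusion_counts, performance_report
from .preprocess import DermoscopyImage, load_image, to_grayscale
from .synthfixtures import DatasetManifest, mock_cnn_decisions

logger = logging.getLogger(__name__)


def hair_params_from_config(cfg: dict) -> HairRemovalParams:
    hr = cfg["hair_removal"]
    return HairRemovalParams(
        se_lengths=tuple(hr["se_lengths"]),
        se_angles=tuple(hr["se_angles"]),
        detect_threshold=hr["detect_threshold"],
        min_elongation=hr["min_elongation"],
        min_length=hr["min_length"],
        median_window=hr["median_window"],
        max_width=hr["max_width"],
    )


def _load_split(manifest: DatasetManifest, split: str, cfg: dict) -> tuple[list, np.ndarray]:
    """Load (and optionally dehair) one split's images; labels 1 = melanoma."""
    rows = manifest.split(split)
    params = hair_params_from_config(cfg)
    images, labels = [], []
    for _, row in rows.iterrows():
        path = (manifest.root or Path(".")) / row["path"]
        try:
            img = load_image(path)
        except (FileNotFoundError, ValueError) as exc:
            raise RuntimeError(f"stage=load split={split} image={row['path']}: {exc}") from exc
        if cfg["hair_removal"]["enabled"]:
            img, _ = remove_hair(img, params)
        images.append(img)
        labels.append(1 if row["label"] == "melanoma" else 0)
    return images, np.asarray(labels, dtype=int)


def _decisions(model: ClassifierModel, images: list[DermoscopyImage]) -> np.ndarray:
    return np.array([predict(model, img).d for img in images], dtype=int)


def run_pipeline(
    manifest: DatasetManifest,
    config: dict | None = None,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> dict:
    """Run the full melanoma-vs-nevus workflow on a manifest.

    Returns the evaluation report as a dict (also written as JSON when
    ``out_dir`` is given): per-classifier and fused performance on the
    testing split, plus the validation accuracies / fusion weights.
    """
    cfg = config or load_config()
    if seed is not None:
        cfg = dict(cfg, seed=seed)
    root_seed = int(cfg["seed"])

    learn_imgs, learn_y = _load_split(manifest, "learning", cfg)
    val_imgs, val_y = _load_split(manifest, "validation", cfg)
    test_imgs, test_y = _load_split(manifest, "testing", cfg)

    mlp_cfg = cfg["classifiers"]["mlp"]
    logger.info("training MLP (%d hidden units)", mlp_cfg["hidden_units"])
    mlp_model = train_mlp_on_images(
        learn_imgs,
        learn_y,
        hidden_units=mlp_cfg["hidden_units"],
        seed=root_seed,
        max_epochs=mlp_cfg["max_epochs"],
        validation_images=val_imgs,
        validation_labels=val_y,
        side=mlp_cfg["input_side"],
    )

    logger.info("training HOG+SVM")
    from .hogfeatures import HogParams

    hog_cfg = cfg["hog"]
    hog = HogParams(
        cell_size=tuple(hog_cfg["cell_size"]),
        block_size=tuple(hog_cfg["block_size"]),
        bins=hog_cfg["bins"],
        signed=hog_cfg["signed"],
        window_size=tuple(hog_cfg["window_size"]),
    )
    svm_model = train_hog_svm(
        [to_grayscale(im) for im in learn_imgs],
        learn_y,
        hog=hog,
        seed=root_seed,
        validation_images=[to_grayscale(im) for im in val_imgs],
        validation_labels=val_y,
        crop=cfg["classifiers"]["hog_svm"]["crop"],
    )

    models: list[tuple[str, ClassifierModel]] = [("mlp", mlp_model)]
    for j, ext in enumerate(cfg["classifiers"]["externals"]):
        table, val_acc = mock_cnn_decisions(manifest, ext["error_rate"], seed=root_seed + j + 1)
        models.append((ext["name"], register_external_classifier(table, val_acc)))
    models.append(("hog_svm", svm_model))

    if cfg["fusion"]["weights"] == "from-validation":
        ens = weights_from_validation(
            [m.validation_accuracy for _, m in models],
            precision=cfg["fusion"]["weight_precision"],
        )
        ens = FusionEnsemble(
            weights=ens.weights,
            threshold_factor=cfg["fusion"]["threshold_factor"],
            weight_precision=cfg["fusion"]["weight_precision"],
        )
    else:
        ens = FusionEnsemble(
            weights=tuple(cfg["fusion"]["weights"]),
            threshold_factor=cfg["fusion"]["threshold_factor"],
            weight_precision=cfg["fusion"]["weight_precision"],
        )

    report: dict = {
        "config": cfg,
        "weights": list(ens.weights),
        "validation_accuracy": {name: m.validation_accuracy for name, m in models},
        "classifiers": {},
    }
    votes = np.zeros((len(models), len(test_imgs)), dtype=int)
    val_votes = np.zeros((len(models), len(val_imgs)), dtype=int)
    for i, (name, model) in enumerate(models):
        votes[i] = _decisions(model, test_imgs)
        val_votes[i] = _decisions(model, val_imgs)
        report["classifiers"][name] = performance_report(
            confusion_counts(votes[i], test_y)
        ).as_dict()
    fused_test = np.array([fuse(ens, votes[:, j]).d for j in range(votes.shape[1])])
    fused_val = np.array([fuse(ens, val_votes[:, j]).d for j in range(val_votes.shape[1])])
    report["fused"] = performance_report(confusion_counts(fused_test, test_y)).as_dict()
    report["fused_validation_accuracy"] = float(np.mean(fused_val == val_y))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        with open(out_dir / "config.json", "w") as fh:
            json.dump(cfg, fh, indent=2, sort_keys=True)
    return report
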