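"""HOG-feature SVM classifier.

The learning matrix stacks one HOG descriptor per training image; a
linear-kernel SVM separates melanoma from common nevus in descriptor
space.  The signed margin is mapped to a [0, 1] melanoma score through a
logistic link so the front-end can treat all classifiers uniformly.
"""

from __future__ import annotations

import numpy as np
from sklearn.svm import SVC

from ..hogfeatures import HogParams, extract_hog
from ..preprocess import DermoscopyImage, GrayImage, resize_gray, to_grayscale
from .base import ClassifierModel, LesionDecision, decision_from_score


def _prepare(g: GrayImage, hog: HogParams, crop: bool) -> GrayImage:
    if crop:
        from ..segmentation import crop_to_lesion, segment_lesion

        g = crop_to_lesion(g, segment_lesion(g))
    if g.pixels.shape != hog.window_size:
        g = resize_gray(g, *hog.window_size)
    return g


def _hog_matrix(images: list[GrayImage], hog: HogParams, crop: bool = False) -> np.ndarray:
    return np.stack([extract_hog(_prepare(g, hog, crop), hog).values for g in images])


def train_hog_svm(
    images: list[GrayImage],
    labels,
    hog: HogParams | None = None,
    seed: int = 0,
    validation_images: list[GrayImage] | None = None,
    validation_labels=None,
    crop: bool = False,
) -> ClassifierModel:
    """Fit a linear SVM on the HOG learning matrix (labels 1 = melanoma).

    With ``crop=True`` each image is first cropped to its segmented lesion
    (the binarized mask centers the feature window; HOG itself still reads
    the grayscale pixels); the same cropping is replayed at predict time.
    """
    hog = hog or HogParams()
    y = np.asarray(labels, dtype=int)
    if len(images) == 0:
        raise ValueError("empty training set")
    if len(images) != y.size:
        raise ValueError("one label per training image required")
    if min(np.sum(y == 1), np.sum(y == 0)) < 1:
        raise ValueError("need examples of both classes")
    x = _hog_matrix(images, hog, crop)
    svc = SVC(kernel="linear", C=1.0, random_state=seed)
    svc.fit(x, y)
    model = ClassifierModel(kind="hog_svm", parameters={"svc": svc, "hog": hog, "crop": crop})
    if validation_images is not None:
        xv = _hog_matrix(validation_images, hog, crop)
        dv = svc.predict(xv)
        model.validation_accuracy = float(np.mean(dv == np.asarray(validation_labels, int)))
    return model


def hog_svm_score(model: ClassifierModel, gray: GrayImage) -> float:
    """Melanoma score: logistic link on the signed SVM margin."""
    hog: HogParams = model.parameters["hog"]
    x = _hog_matrix([gray], hog, model.parameters.get("crop", False))
    margin = float(model.parameters["svc"].decision_function(x)[0])
    return 1.0 / (1.0 + np.exp(-margin))


def predict_hog_svm(model: ClassifierModel, img: DermoscopyImage) -> LesionDecision:
    return decision_from_score(hog_svm_score(model, to_grayscale(img)))
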