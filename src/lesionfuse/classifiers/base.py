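"""Classifier containers and the uniform prediction front-end.

Three classifier kinds share one interface: the in-package feed-forward
network (``mlp``), the HOG-feature SVM (``hog_svm``), and externally trained
CNNs whose per-image decisions are ingested as a lookup table
(``external_cnn``).  ``predict`` routes an image through the model's
recorded preprocessing and returns a hard decision plus a melanoma score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

from ..preprocess import DermoscopyImage

#: Score ties at exactly 0.5 resolve to melanoma (errs toward sensitivity).
DECISION_CUTOFF = 0.5

KINDS = ("mlp", "hog_svm", "external_cnn")


@dataclass(frozen=True)
class LesionDecision:
    """d = 1 flags melanoma, 0 a common nevus; score is the melanoma
    probability (or margin mapped to [0,1])."""

    d: int
    score: float

    def __post_init__(self) -> None:
        if self.d not in (0, 1):
            raise ValueError(f"decision must be 0 or 1, got {self.d!r}")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must lie in [0, 1], got {self.score!r}")


@dataclass
class ClassifierModel:
    kind: str
    parameters: Any
    validation_accuracy: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}; expected one of {KINDS}")
        if self.validation_accuracy is not None and not (0.0 <= self.validation_accuracy <= 1.0):
            raise ValueError("validation_accuracy must lie in [0, 1]")


def decision_from_score(score: float) -> LesionDecision:
    return LesionDecision(d=int(score >= DECISION_CUTOFF), score=float(score))


def predict(model: ClassifierModel, img: DermoscopyImage) -> LesionDecision:
    """Uniform front-end: preprocess per the model's pipeline and decide.

    Deterministic for a fixed model and image.  External models echo their
    registered decision and raise ``KeyError`` for an unknown image id.
    """
    if model.kind == "mlp":
        from .mlp import predict_mlp

        return predict_mlp(model, img)
    if model.kind == "hog_svm":
        from .svm import predict_hog_svm

        return predict_hog_svm(model, img)
    if model.kind == "external_cnn":
        from .external import predict_external

        return predict_external(model, img)
    raise ValueError(f"unknown classifier kind {model.kind!r}")
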