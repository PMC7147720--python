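"""Plug-in contract for externally trained CNN classifiers.

Fine-tuning a pretrained CNN happens outside this package; what fusion
needs is only (a) the per-image decisions the CNN produced and (b) its
validation accuracy, which becomes its fusion weight.  This module ingests
those so external CNNs behave exactly like native classifiers.
"""

from __future__ import annotations

from typing import Mapping

from ..preprocess import DermoscopyImage
from .base import ClassifierModel, LesionDecision


def register_external_classifier(
    decisions: Mapping[str, LesionDecision], validation_accuracy: float
) -> ClassifierModel:
    """Wrap a table of per-image decisions keyed by image id.

    ``validation_accuracy`` must lie in [0, 1].  An empty table is a valid
    model; it simply errors on any predict.
    """
    if not (0.0 <= validation_accuracy <= 1.0):
        raise ValueError(f"validation_accuracy must lie in [0, 1], got {validation_accuracy}")
    table = dict(decisions)
    for k, v in table.items():
        if not isinstance(v, LesionDecision):
            raise ValueError(f"decision for id {k!r} is not a LesionDecision")
    return ClassifierModel(
        kind="external_cnn",
        parameters={"decisions": table},
        validation_accuracy=float(validation_accuracy),
    )


def predict_external(model: ClassifierModel, img: DermoscopyImage) -> LesionDecision:
    table = model.parameters["decisions"]
    if img.source_id not in table:
        raise KeyError(
            f"no registered decision for image id {img.source_id!r} "
            f"({len(table)} ids registered)"
        )
    return table[img.source_id]
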