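"""Accuracy-weighted decision fusion.

Each of the n classifiers casts a hard vote d_i (1 = melanoma) carrying a
weight w_i equal to its validation-phase accuracy.  The global index

    W = sum_i w_i * d_i

is compared against a fixed fraction of the unanimous score
W_max = sum_i w_i; the ensemble declares melanoma when

    W >= threshold_factor * W_max        (default factor 0.7).

With five classifiers whose accuracies sit near 0.9, this rule coincides
with a 4-of-5 majority.  Threshold comparison uses full-precision
arithmetic; the 2-decimal threshold is presentation only, so rounding can
never flip a boundary case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._util import round_half_away
from .classifiers.base import ClassifierModel, LesionDecision, predict
from .metrics import PerformanceReport
from .preprocess import DermoscopyImage

logger = logging.getLogger(__name__)

#: Printed weight sets of the reference ensembles (NN, three CNNs, HOG+SVM).
PH2_WEIGHTS = (0.93, 0.9, 0.9, 0.9, 0.93)
ISIC_WEIGHTS = (0.88, 0.92, 0.88, 0.87, 0.9)

_EPS = 1e-12


@dataclass(frozen=True)
class FusionEnsemble:
    """Ordered classifier weights plus the threshold factor."""

    weights: tuple[float, ...]
    threshold_factor: float = 0.7
    weight_precision: int = 2

    def __post_init__(self) -> None:
        w = tuple(float(x) for x in self.weights)
        if len(w) < 1:
            raise ValueError("ensemble needs at least one weight")
        if any(not (0.0 <= x <= 1.0) for x in w):
            raise ValueError("weights must lie in [0, 1]")
        if not (0.0 < self.threshold_factor <= 1.0):
            raise ValueError("threshold_factor must lie in (0, 1]")
        object.__setattr__(self, "weights", w)

    @property
    def size(self) -> int:
        return len(self.weights)


DecisionVector = Sequence[int]


def _check_decisions(ens: FusionEnsemble, d: DecisionVector) -> np.ndarray:
    dv = np.asarray(d, dtype=float)
    if dv.ndim != 1 or dv.size != ens.size:
        raise ValueError(f"decision vector length {dv.size} != ensemble size {ens.size}")
    if not np.isin(dv, (0.0, 1.0)).all():
        raise ValueError("decisions must be 0 or 1")
    return dv


def weights_from_validation(
    reports: Sequence[PerformanceReport | float], precision: int = 2
) -> FusionEnsemble:
    """Build an ensemble whose weight i is classifier i's validation accuracy.

    Accepts performance reports or bare accuracy fractions; each accuracy is
    rounded half-away-from-zero to ``precision`` decimals, order preserved.
    """
    if len(reports) < 1:
        raise ValueError("need at least one validation report")
    accs = [r.accuracy if isinstance(r, PerformanceReport) else float(r) for r in reports]
    w = tuple(round_half_away(a, precision) for a in accs)
    return FusionEnsemble(weights=w, weight_precision=precision)


def global_index(ens: FusionEnsemble, d: DecisionVector) -> float:
    """W = sum of the weights of the classifiers voting melanoma."""
    dv = _check_decisions(ens, d)
    return float(np.dot(np.asarray(ens.weights), dv))


def w_max(ens: FusionEnsemble) -> float:
    """Unanimous-decision score: the sum of all weights."""
    return float(np.sum(ens.weights))


def decision_threshold(ens: FusionEnsemble) -> float:
    """The melanoma threshold ``factor * W_max`` reported at 2 decimals.

    Presentation value only; :func:`fuse` compares at full precision.
    """
    return round_half_away(ens.threshold_factor * w_max(ens), 2)


def fuse(ens: FusionEnsemble, d: DecisionVector) -> LesionDecision:
    """Global verdict: melanoma iff W >= factor * W_max (full precision)."""
    w = global_index(ens, d)
    wm = w_max(ens)
    thr = ens.threshold_factor * wm
    is_me = w >= thr - _EPS
    # dot and sum can round differently, so clamp W/W_max into [0, 1]
    score = min(1.0, max(0.0, w / wm)) if wm > 0 else 0.0
    return LesionDecision(d=int(is_me), score=float(score))


def classify_image(
    models: Sequence[ClassifierModel], ens: FusionEnsemble, img: DermoscopyImage
) -> LesionDecision:
    """Run every classifier on the image and fuse their hard votes."""
    if len(models) != ens.size:
        raise ValueError(f"{len(models)} models for {ens.size} weights")
    votes = [predict(m, img).d for m in models]
    logger.debug("classify_image %s: votes=%s", img.source_id, votes)
    return fuse(ens, votes)
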