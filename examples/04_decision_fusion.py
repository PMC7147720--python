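"""Accuracy-weighted vote fusion with the published five-classifier weights.

Each classifier votes melanoma (1) or nevus (0); the vote carries the
classifier's validation accuracy as weight.  The ensemble declares
melanoma when the weighted sum W reaches 70% of the unanimous score W_max.
"""

import itertools

from lesionfuse.fusion import (
    PH2_WEIGHTS,
    FusionEnsemble,
    decision_threshold,
    fuse,
    global_index,
    w_max,
)

ens = FusionEnsemble(weights=PH2_WEIGHTS)  # (0.93, 0.9, 0.9, 0.9, 0.93)
print(f"W_max     = {w_max(ens):.2f}")
print(f"threshold = {decision_threshold(ens):.2f}  (0.7 * W_max)")

for votes in ([1, 1, 1, 1, 1], [1, 0, 1, 1, 1], [1, 0, 1, 1, 0], [0, 0, 0, 0, 0]):
    out = fuse(ens, votes)
    verdict = "melanoma" if out.d else "common nevus"
    print(f"votes {votes}: W = {global_index(ens, votes):.2f} -> {verdict}")

agree = all(
    fuse(ens, list(v)).d == (sum(v) >= 4) for v in itertools.product((0, 1), repeat=5)
)
print(f"equivalent to a 4-of-5 majority over all 32 vote patterns: {agree}")
# With weights this close together the threshold rule coincides exactly
# with requiring four of the five classifiers to vote melanoma.
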