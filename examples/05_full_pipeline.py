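"""The whole workflow on a small synthetic dataset.

Generates a train/validation/test image set, removes hair, trains the
feed-forward network and the HOG+SVM, simulates three external CNNs,
derives fusion weights from validation accuracies, and reports fused
performance on the held-out testing split.

Runs at reduced frame size so it finishes in well under a minute; the
toolkit's reference conditions use full 560x768 frames (see the methods
note).
"""

import tempfile
from pathlib import Path

from lesionfuse import synthfixtures as sf
from lesionfuse.config import load_config
from lesionfuse.pipeline import run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    manifest = sf.generate_dataset("ph2", Path(tmp), seed=17, size=(140, 192))
    report = run_pipeline(manifest, load_config(), seed=17)

print("validation accuracies (become fusion weights):")
for name, acc in report["validation_accuracy"].items():
    print(f"  {name:8s} {acc:.4f}")
print(f"fusion weights: {report['weights']}")
print(f"fused validation accuracy: {report['fused_validation_accuracy']:.4f}")
print(f"fused testing accuracy:    {report['fused']['accuracy']:.4f}")
print(f"fused testing sensitivity: {report['fused']['sensitivity']:.4f}")
print(f"fused testing specificity: {report['fused']['specificity']:.4f}")
# The fused verdict needs 4 of the 5 classifiers to agree, which suppresses
# individual classifiers' uncorrelated errors on the testing split.
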