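"""Headless CNN feature extraction with an injected backbone.

The deep extractor is framework-agnostic: any callable mapping a
prepared (H, W, 3) array to a final activation volume can be injected.
Here a stub stands in for MobileNet's convolutional stack; with
TensorFlow installed, `load_keras_backbone("MobileNet")` provides the
real architecture with the same contract.
"""

import numpy as np

from eegmap import (
    BACKBONE_REGISTRY,
    BackboneSpec,
    PipelineConfig,
    SyntheticConfig,
    extract_deep,
    generate_recording,
    recording_to_image,
)

print("registered backbones (feature dimensions):")
for name, (size, dim) in sorted(BACKBONE_REGISTRY.items()):
    print(f"  {name:18s} input {size[0]}x{size[1]}  -> {dim} features")

rec = generate_recording(SyntheticConfig(), "alcoholic", seed=1)
image = recording_to_image(rec, PipelineConfig())

spec = BackboneSpec.from_registry("MobileNet")
rng = np.random.default_rng(0)
stub = lambda prepared: rng.normal(size=(7, 7, spec.feature_dim))  # noqa: E731

fv = extract_deep(image, spec, stub)
print(f"\nMobileNet stub: {len(fv)}-dimensional feature vector "
      f"(global average pool of a 7x7x{spec.feature_dim} activation stack)")
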