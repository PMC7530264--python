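"""Headless CNN feature extraction via injected backbones.

Transfer-learning extraction treats an ImageNet-trained convolutional
network, classification head removed, as a fixed feature map: the
heat-map image is resized to the backbone's canonical input, replicated
to 3 channels, pushed through the convolutional stack, and the final
activation volume is global-average-pooled into a flat vector.

The backbone itself is *injected* as a plain callable (prepared array ->
activation array), so this module has no deep-learning framework
dependency: tests run against stubs, and :func:`load_torchvision_backbone`
instantiates real architectures when torch/torchvision happen to be
installed. The registry pins the expected feature dimensionality of the
12 supported architectures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from skimage.transform import resize

from .core import ConfigurationError, FeatureVector, HeatmapImage

#: name -> (canonical input size, feature dimension after global average
#: pooling of the last convolutional stack)
BACKBONE_REGISTRY: dict[str, tuple[tuple[int, int], int]] = {
    "DenseNet121": ((224, 224), 1024),
    "DenseNet169": ((224, 224), 1664),
    "DenseNet201": ((224, 224), 1920),
    "InceptionResNetV2": ((299, 299), 1536),
    "InceptionV3": ((299, 299), 2048),
    "MobileNet": ((224, 224), 1024),
    "NASNetLarge": ((331, 331), 4032),
    "NASNetMobile": ((224, 224), 1056),
    "ResNet50": ((224, 224), 2048),
    "VGG16": ((224, 224), 512),
    "VGG19": ((224, 224), 512),
    "Xception": ((299, 299), 2048),
}

#: per-backbone pixel scaling convention: "tf" maps [0,255] -> [-1,1],
#: "torch" maps to [0,1] then standardizes with the ImageNet statistics,
#: "caffe" subtracts the ImageNet channel means (no scaling).
SCALING_CONVENTIONS: dict[str, str] = {
    "DenseNet121": "torch",
    "DenseNet169": "torch",
    "DenseNet201": "torch",
    "InceptionResNetV2": "tf",
    "InceptionV3": "tf",
    "MobileNet": "tf",
    "NASNetLarge": "tf",
    "NASNetMobile": "tf",
    "ResNet50": "caffe",
    "VGG16": "caffe",
    "VGG19": "caffe",
    "Xception": "tf",
}

_IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
_IMAGENET_SD = np.array([0.229, 0.224, 0.225])


def feature_dim(name: str) -> int:
    """Registered feature dimensionality of a backbone."""
    if name not in BACKBONE_REGISTRY:
        raise ConfigurationError(
            f"unknown backbone {name!r}; registered: {sorted(BACKBONE_REGISTRY)}"
        )
    return BACKBONE_REGISTRY[name][1]


def input_size(name: str) -> tuple[int, int]:
    """Canonical (H, W) input size of a backbone."""
    if name not in BACKBONE_REGISTRY:
        raise ConfigurationError(
            f"unknown backbone {name!r}; registered: {sorted(BACKBONE_REGISTRY)}"
        )
    return BACKBONE_REGISTRY[name][0]


@dataclass
class BackboneSpec:
    """Identity + geometry of a feature-extraction backbone."""

    name: str
    input_size: tuple[int, int]
    feature_dim: int
    pretrained: bool = False

    def __post_init__(self) -> None:
        if self.name in BACKBONE_REGISTRY:
            expected = BACKBONE_REGISTRY[self.name][1]
            if self.feature_dim != expected:
                raise ConfigurationError(
                    f"{self.name}: feature_dim {self.feature_dim} does not match "
                    f"the registry value {expected}"
                )
        if self.input_size[0] <= 0 or self.input_size[1] <= 0:
            raise ConfigurationError("input_size must be positive")

    @classmethod
    def from_registry(cls, name: str, pretrained: bool = False) -> "BackboneSpec":
        return cls(name=name, input_size=input_size(name),
                   feature_dim=feature_dim(name), pretrained=pretrained)


def prepare_image(image, spec: BackboneSpec) -> np.ndarray:
    """Resize, replicate to 3 channels, and scale per the backbone convention.

    Returns an (H, W, 3) float array. Resizing is bilinear; an image
    already at the target size passes through pixel-identically.
    """
    if isinstance(image, HeatmapImage):
        arr = image.pixels
    else:
        arr = np.asarray(image)
    if arr.ndim != 2 or arr.size == 0:
        raise ConfigurationError("expected a non-empty 2-D grayscale image")
    target = spec.input_size
    if target[0] <= 0 or target[1] <= 0:
        raise ConfigurationError("zero-size resize target")
    arr = arr.astype(float)
    if arr.shape != target:
        arr = resize(arr, target, order=1, mode="edge", anti_aliasing=False,
                     preserve_range=True)
    rgb = np.repeat(arr[:, :, None], 3, axis=2)
    convention = SCALING_CONVENTIONS.get(spec.name, "tf")
    if convention == "tf":
        return rgb / 127.5 - 1.0
    if convention == "torch":
        return (rgb / 255.0 - _IMAGENET_MEAN) / _IMAGENET_SD
    # caffe: mean subtraction in 0-255 space
    return rgb - _IMAGENET_MEAN * 255.0


def extract_deep(
    image,
    spec: BackboneSpec,
    backbone: Callable[[np.ndarray], np.ndarray],
) -> FeatureVector:
    """Run an injected backbone on a prepared image and flatten its output.

    The backbone maps the prepared (H, W, 3) array to either a final
    activation volume (h, w, channels), which is global-average-pooled
    over the spatial axes, or directly to a 1-D vector. The result must
    match the spec's ``feature_dim``.
    """
    prepared = prepare_image(image, spec)
    activation = np.asarray(backbone(prepared), dtype=float)
    if activation.ndim == 3:
        vector = activation.mean(axis=(0, 1))
    elif activation.ndim == 1:
        vector = activation
    else:
        raise ConfigurationError(
            f"backbone returned ndim={activation.ndim}; expected a (h, w, c) "
            "activation volume or a flat vector"
        )
    if vector.size != spec.feature_dim:
        raise ConfigurationError(
            f"{spec.name}: backbone produced {vector.size} features but the "
            f"registry expects {spec.feature_dim}"
        )
    names = [f"{spec.name.lower()}_{i:04d}" for i in range(vector.size)]
    return FeatureVector(extractor_id=spec.name, names=names, values=vector)


def load_keras_backbone(name: str, pretrained: bool = False):
    """Instantiate a real Keras applications backbone as an injectable callable.

    All 12 registered architectures exist in ``tf.keras.applications``
    and reproduce the registry dimensionalities with their classifier
    head removed (``include_top=False``). Weights are randomly
    initialized unless ``pretrained`` (which downloads ImageNet weights
    and is never needed by tests). Raises ImportError with guidance when
    TensorFlow is not installed.
    """
    try:
        from tensorflow.keras import applications
    except ImportError as exc:  # pragma: no cover - exercised only with tensorflow
        raise ImportError(
            "load_keras_backbone requires TensorFlow; alternatively inject "
            "any callable into extract_deep"
        ) from exc

    factories = {
        "DenseNet121": applications.DenseNet121,
        "DenseNet169": applications.DenseNet169,
        "DenseNet201": applications.DenseNet201,
        "InceptionResNetV2": applications.InceptionResNetV2,
        "InceptionV3": applications.InceptionV3,
        "MobileNet": applications.MobileNet,
        "NASNetLarge": applications.NASNetLarge,
        "NASNetMobile": applications.NASNetMobile,
        "ResNet50": applications.ResNet50,
        "VGG16": applications.VGG16,
        "VGG19": applications.VGG19,
        "Xception": applications.Xception,
    }
    if name not in factories:
        raise ConfigurationError(
            f"no Keras factory for {name!r}; available: {sorted(factories)}"
        )
    size = input_size(name)
    model = factories[name](
        include_top=False,
        weights="imagenet" if pretrained else None,
        input_shape=(size[0], size[1], 3),
    )

    def backbone(prepared: np.ndarray) -> np.ndarray:
        out = model(prepared[None].astype(np.float32)).numpy()
        return out[0]  # (h, w, channels); extract_deep pools spatially

    return backbone
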