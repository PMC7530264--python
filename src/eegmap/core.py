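"""Core domain containers shared by every pipeline stage.

The pipeline moves a multichannel EEG recording (µV, channels x samples)
through channel selection, outlier clipping and 8-bit quantization into a
grayscale heat-map image whose texture encodes the frequency content of
each channel. These containers carry the data plus the metadata (channel
names, layout, provenance) each stage needs to stay self-describing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

VALID_LABELS = ("control", "alcoholic", "unknown")


class EEGMapError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EEGMapError):
    """An invalid configuration value or combination."""


class ParseError(EEGMapError):
    """A file could not be parsed; the message names the offending line."""


class PipelineStageError(EEGMapError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage {stage}] {message}")


@dataclass
class Recording:
    """A multichannel EEG recording in microvolts.

    ``data`` is a (n_channels, n_samples) float array; row *i* is the
    time series of ``channel_names[i]``.
    """

    channel_names: list[str]
    sampling_rate: float
    data: np.ndarray
    label: str = "unknown"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ConfigurationError(
                f"recording data must be 2-D (channels x samples), got ndim={self.data.ndim}"
            )
        if self.data.shape[0] != len(self.channel_names):
            raise ConfigurationError(
                f"{len(self.channel_names)} channel names but {self.data.shape[0]} data rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ConfigurationError("channel names must be unique")
        if self.label not in VALID_LABELS:
            raise ConfigurationError(
                f"label {self.label!r} not in {VALID_LABELS}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ConfigurationError("recording contains non-finite values")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not present") from None
        return self.data[idx]


@dataclass
class QuantizedRecording:
    """A recording after min-max normalization and integer quantization.

    Values are integers in ``[0, quant_levels - 1]``.
    """

    channel_names: list[str]
    data: np.ndarray
    quant_levels: int = 256
    label: str = "unknown"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ConfigurationError("quantized data must be an integer array")
        if self.data.shape[0] != len(self.channel_names):
            raise ConfigurationError("channel count mismatch")
        if self.data.size and (self.data.min() < 0 or self.data.max() >= self.quant_levels):
            raise ConfigurationError(
                f"quantized values outside [0, {self.quant_levels - 1}]"
            )


@dataclass
class HeatmapImage:
    """8-bit grayscale heat map: time runs down rows, channels across columns.

    Each channel occupies a contiguous block of ``block_width`` identical
    columns, so a low-frequency channel renders as a smooth vertical band
    and a high-frequency channel as a rough one.
    """

    pixels: np.ndarray
    layout: list[tuple[str, int, int]] = field(default_factory=list)
    subject_id: str = ""
    label: str = "unknown"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ConfigurationError("heatmap pixels must be a 2-D grid")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise ConfigurationError("heatmap pixels must be integers")
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > 255):
            raise ConfigurationError("heatmap pixels must lie in [0, 255]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class FeatureVector:
    """A named, ordered real-valued feature vector tagged with its extractor."""

    extractor_id: str
    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ConfigurationError("feature values must be 1-D")
        if len(self.names) != self.values.size:
            raise ConfigurationError(
                f"{len(self.names)} names but {self.values.size} values"
            )
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("feature values must be finite")

    def __len__(self) -> int:
        return self.values.size

    @staticmethod
    def concatenate(parts: Sequence["FeatureVector"], extractor_id: str) -> "FeatureVector":
        names = [n for p in parts for n in p.names]
        values = np.concatenate([p.values for p in parts]) if parts else np.empty(0)
        return FeatureVector(extractor_id=extractor_id, names=names, values=values)
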