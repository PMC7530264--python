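"""Heat-map composition and 8-bit grayscale PNG IO.

A quantized recording becomes a 2-D image: time runs down the rows
(``time_length`` of them), and each channel fills a block of
``block_width`` identical columns, so the default 11-channel, 1024-sample
configuration yields a 1024 x 352 image. High-frequency channels render
as rough texture blocks, low-frequency channels as smooth ones — the
texture descriptors downstream feed on exactly that distinction.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .core import ConfigurationError, HeatmapImage, QuantizedRecording
from .preprocess import PipelineConfig


def compose_heatmap(
    q: QuantizedRecording, config: PipelineConfig | None = None
) -> HeatmapImage:
    """Compose the channel-block heat map from a quantized recording.

    Channel ``c`` occupies columns ``[c*block_width, (c+1)*block_width)``,
    every column equal to that channel's quantized series running down
    the rows. Recordings longer than ``time_length`` are truncated; a
    shorter recording raises unless ``pad_mode="edge"`` extends it with
    its last value.
    """
    config = config or PipelineConfig()
    if q.data.size == 0 or q.data.shape[1] == 0:
        raise ConfigurationError("every channel needs at least one sample")
    if q.quant_levels > 256:
        raise ConfigurationError("heat maps are 8-bit; quant_levels must be <= 256")
    n_samples = q.data.shape[1]
    data = q.data
    if n_samples > config.time_length:
        data = data[:, : config.time_length]
    elif n_samples < config.time_length:
        if config.pad_mode != "edge":
            raise ConfigurationError(
                f"recording has {n_samples} samples but time_length is "
                f"{config.time_length}; enable pad_mode='edge' to pad"
            )
        data = np.pad(data, ((0, 0), (0, config.time_length - n_samples)), mode="edge")
    # (channels, time) -> (time, channels), then widen each channel column
    pixels = np.repeat(data.T, config.block_width, axis=1).astype(np.uint8)
    layout = [
        (name, c * config.block_width, (c + 1) * config.block_width)
        for c, name in enumerate(q.channel_names)
    ]
    return HeatmapImage(pixels=pixels, layout=layout, subject_id=q.subject_id, label=q.label)


def decompose_heatmap(image: HeatmapImage) -> np.ndarray:
    """Invert composition: average each channel block back to its series."""
    if not image.layout:
        raise ConfigurationError("image has no channel layout metadata")
    series = [image.pixels[:, start:stop].mean(axis=1) for _, start, stop in image.layout]
    return np.vstack(series)


def write_png(image: HeatmapImage, path: str | Path) -> None:
    """Write the heat map as an 8-bit single-channel (mode L) PNG."""
    Image.fromarray(image.pixels.astype(np.uint8), mode="L").save(Path(path), format="PNG")


def read_png(path: str | Path) -> HeatmapImage:
    """Read an 8-bit grayscale PNG back into a HeatmapImage.

    Layout metadata is not stored in the PNG, so the returned image has
    an empty layout; pixel content round-trips exactly.
    """
    with Image.open(Path(path)) as im:
        if im.mode != "L":
            raise ConfigurationError(
                f"{path}: expected 8-bit grayscale (mode L) PNG, got mode {im.mode!r}"
            )
        pixels = np.asarray(im, dtype=np.uint8)
    return HeatmapImage(pixels=pixels, layout=[], subject_id=Path(path).stem)
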