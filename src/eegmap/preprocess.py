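"""Signal conditioning: channel selection, outlier removal, quantization.

The conditioning stage reduces a 64-channel recording to the 11 channels
with the most intense activity (highest mean per-channel variance across
subjects), removes artifact excursions beyond +/-73.3 µV (head and eye
movements), min-max normalizes the selected signals jointly to [0, 1]
and rescales them to 8-bit integers, ready for image composition.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from .core import ConfigurationError, QuantizedRecording, Recording

#: The 11 high-variance channels used by the default configuration
#: (duplicate tokens in common listings collapse to 11 unique labels).
DEFAULT_FIXED_CHANNELS: tuple[str, ...] = (
    "FP1", "FP2", "F7", "F8", "T7", "T8", "CZ", "C3", "C4", "CP5", "CP6",
)

#: Outlier threshold in µV; excursions beyond it are treated as movement
#: artifacts rather than neural signal.
DEFAULT_CLIP_THRESHOLD = 73.3


@dataclass
class PipelineConfig:
    """Configuration of the conditioning + imaging stages.

    channel_mode
        ``"fixed-list"`` keeps ``fixed_channels`` in the given order;
        ``"top-k"`` keeps the ``top_k`` channels with the highest mean
        variance (ranking order).
    outlier_mode
        ``"clip"`` saturates at +/-``clip_threshold``; ``"drop"``
        replaces offending samples by linear interpolation of their
        nearest in-range neighbors.
    normalization_scope
        ``"recording"`` min-max normalizes all selected channels
        jointly; ``"channel"`` normalizes each channel on its own.
    """

    channel_mode: str = "fixed-list"
    fixed_channels: tuple[str, ...] = DEFAULT_FIXED_CHANNELS
    top_k: int = 11
    clip_threshold: float = DEFAULT_CLIP_THRESHOLD
    outlier_mode: str = "clip"
    time_length: int = 1024
    block_width: int = 32
    quant_levels: int = 256
    normalization_scope: str = "recording"
    pad_mode: str | None = None

    def __post_init__(self) -> None:
        if self.channel_mode not in ("fixed-list", "top-k"):
            raise ConfigurationError(f"unknown channel_mode {self.channel_mode!r}")
        if self.outlier_mode not in ("clip", "drop"):
            raise ConfigurationError(f"unknown outlier_mode {self.outlier_mode!r}")
        if self.normalization_scope not in ("recording", "channel"):
            raise ConfigurationError(
                f"unknown normalization_scope {self.normalization_scope!r}"
            )
        if self.clip_threshold <= 0:
            raise ConfigurationError("clip_threshold must be positive")
        if self.top_k < 1:
            raise ConfigurationError("top_k must be >= 1")
        if self.quant_levels < 2:
            raise ConfigurationError("quant_levels must be >= 2")
        if len(set(self.fixed_channels)) != len(self.fixed_channels):
            raise ConfigurationError("fixed_channels must be unique")
        if self.pad_mode not in (None, "edge"):
            raise ConfigurationError(f"unknown pad_mode {self.pad_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        for key in ("fixed_channels",):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fixed_channels"] = list(self.fixed_channels)
        return d


def channel_variance_ranking(
    recordings: list[Recording],
) -> list[tuple[str, float]]:
    """Rank channels by their mean sample variance across recordings.

    Variance is the per-channel sample variance (ddof=1 when a channel
    has more than one sample) computed per recording, then averaged over
    recordings. The result is sorted by descending mean variance; ties
    break lexicographically by channel name.
    """
    if not recordings:
        raise ConfigurationError("need at least one recording")
    names = recordings[0].channel_names
    name_set = set(names)
    for rec in recordings[1:]:
        if set(rec.channel_names) != name_set:
            missing = sorted(name_set ^ set(rec.channel_names))
            raise ConfigurationError(
                f"recordings have inconsistent channel sets; difference: {missing}"
            )
    acc = dict.fromkeys(names, 0.0)
    for rec in recordings:
        ddof = 1 if rec.n_samples > 1 else 0
        variances = rec.data.var(axis=1, ddof=ddof)
        for name, v in zip(rec.channel_names, variances):
            acc[name] += float(v)
    n = len(recordings)
    ranked = [(name, total / n) for name, total in acc.items()]
    ranked.sort(key=lambda item: (-item[1], item[0]))
    return ranked


def select_channels(
    recording: Recording,
    config: PipelineConfig,
    ranking: list[tuple[str, float]] | None = None,
) -> Recording:
    """Restrict a recording to the configured channel subset.

    In ``fixed-list`` mode rows follow ``config.fixed_channels``; in
    ``top-k`` mode rows follow the first ``top_k`` entries of
    ``ranking`` (computed from the recording itself when not supplied).
    """
    if config.channel_mode == "fixed-list":
        wanted = list(config.fixed_channels)
    else:
        if ranking is None:
            ranking = channel_variance_ranking([recording])
        wanted = [name for name, _ in ranking[: config.top_k]]
    indices = []
    for name in wanted:
        if name not in recording.channel_names:
            raise ConfigurationError(f"channel {name!r} not present in recording")
        indices.append(recording.channel_names.index(name))
    return Recording(
        channel_names=wanted,
        sampling_rate=recording.sampling_rate,
        data=recording.data[indices],
        label=recording.label,
        subject_id=recording.subject_id,
    )


def remove_outliers(
    signal: np.ndarray,
    threshold: float = DEFAULT_CLIP_THRESHOLD,
    mode: str = "clip",
) -> np.ndarray:
    """Remove samples beyond +/-``threshold`` µV from a 1-D series.

    ``clip`` saturates them at the threshold (idempotent, length
    preserving); ``drop`` replaces them by linear interpolation of the
    nearest in-range neighbors, with endpoint excursions taking the
    nearest valid value.
    """
    if threshold <= 0:
        raise ConfigurationError("threshold must be positive")
    signal = np.asarray(signal, dtype=float)
    if mode == "clip":
        return np.clip(signal, -threshold, threshold)
    if mode == "drop":
        bad = np.abs(signal) > threshold
        if bad.all():
            raise ConfigurationError("all samples out of range; nothing to interpolate from")
        if not bad.any():
            return signal.copy()
        x = np.arange(signal.size)
        return np.interp(x, x[~bad], signal[~bad])
    raise ConfigurationError(f"unknown outlier mode {mode!r}")


def normalize_quantize(recording: Recording, config: PipelineConfig) -> QuantizedRecording:
    """Min-max normalize to [0, 1] and quantize to ``quant_levels`` integers.

    By default the min and max are taken over all selected channels
    jointly, so relative amplitudes between channels survive; a
    constant recording (zero range) maps to all zeros. Quantized value
    is ``floor(x * (levels - 1) + 0.5)`` (round half up).
    """
    if recording.data.size == 0:
        raise ConfigurationError("empty recording")
    if not np.all(np.isfinite(recording.data)):
        raise ConfigurationError("recording contains non-finite values")
    data = recording.data
    if config.normalization_scope == "recording":
        lo, hi = data.min(), data.max()
        span = hi - lo
        unit = np.zeros_like(data) if span == 0 else (data - lo) / span
    else:
        lo = data.min(axis=1, keepdims=True)
        span = data.max(axis=1, keepdims=True) - lo
        unit = np.where(span == 0, 0.0, (data - lo) / np.where(span == 0, 1.0, span))
    quantized = np.floor(unit * (config.quant_levels - 1) + 0.5).astype(np.int64)
    return QuantizedRecording(
        channel_names=list(recording.channel_names),
        data=quantized,
        quant_levels=config.quant_levels,
        label=recording.label,
        subject_id=recording.subject_id,
    )


def preprocess_recording(
    recording: Recording,
    config: PipelineConfig | None = None,
    ranking: list[tuple[str, float]] | None = None,
) -> QuantizedRecording:
    """Full conditioning: select channels, remove outliers, quantize."""
    config = config or PipelineConfig()
    selected = select_channels(recording, config, ranking=ranking)
    cleaned = np.vstack([
        remove_outliers(row, config.clip_threshold, config.outlier_mode)
        for row in selected.data
    ])
    cleaned_rec = Recording(
        channel_names=selected.channel_names,
        sampling_rate=selected.sampling_rate,
        data=cleaned,
        label=selected.label,
        subject_id=selected.subject_id,
    )
    return normalize_quantize(cleaned_rec, config)
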