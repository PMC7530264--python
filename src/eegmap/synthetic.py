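"""Synthetic two-class EEG generator.

Real recordings of the kind this pipeline targets separate an alcoholic
group from a control group by the frequency content of a handful of
high-variance channels: the alcoholic class shows relatively more
high-frequency (beta/gamma range) activity, the control class more
low-frequency activity. The generator reproduces exactly the statistical
structure the downstream stages rely on:

* 64 named 10-20/10-10 channels sampled at 256 Hz;
* class-dependent band-limited signal confined to a configurable set of
  "active" channels (defaults to the 11 channels the pipeline selects),
  so per-channel variance ranking singles them out;
* sporadic artifact excursions at +/-``artifact_amplitude`` µV, beyond
  the +/-73.3 µV outlier threshold, emulating head and eye movements.

It does not attempt physiological realism (no 1/f background, no event
related potentials, no eye-blink morphology): the class signal is a sum
of ``n_components`` equal-amplitude sinusoids whose frequencies are drawn
on the DFT grid of the recording inside the class band, which makes the
spectral support of the noiseless signal exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ConfigurationError, Recording

#: Default channel list: 64 unique 10-10 labels including the 11 channels
#: selected by the default pipeline configuration.
DEFAULT_CHANNELS: tuple[str, ...] = (
    "FP1", "FPZ", "FP2",
    "AF7", "AF3", "AFZ", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "FZ", "F2", "F4", "F6", "F8",
    "FT9", "FT7", "FC5", "FC3", "FC1", "FCZ", "FC2", "FC4", "FC6", "FT8", "FT10",
    "T7", "C5", "C3", "C1", "CZ", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POZ", "PO4", "PO8",
    "O1", "OZ", "O2", "IZ",
)

#: The 11 high-variance channels the pipeline selects by default.
ACTIVE_CHANNELS: tuple[str, ...] = (
    "FP1", "FP2", "F7", "F8", "T7", "T8", "CZ", "C3", "C4", "CP5", "CP6",
)


@dataclass
class SyntheticConfig:
    """Parameters of the two-class generator.

    ``control_band`` / ``alcoholic_band`` are Hz intervals holding the
    class signal; ``band_amplitude`` is the total peak amplitude (µV) of
    the multi-sinusoid, split equally over ``n_components`` components.
    ``amplitude_ratio`` scales the alcoholic-class amplitude relative to
    the control class (1.0 = equal power in both classes).
    """

    n_channels: int = 64
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    sampling_rate: float = 256.0
    n_samples: int = 1024
    active_channels: tuple[str, ...] = ACTIVE_CHANNELS
    control_band: tuple[float, float] = (1.0, 7.0)
    alcoholic_band: tuple[float, float] = (20.0, 50.0)
    band_amplitude: float = 20.0
    amplitude_ratio: float = 1.0
    n_components: int = 3
    noise_sd: float = 5.0
    artifact_rate: float = 0.001
    artifact_amplitude: float = 90.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ConfigurationError("n_samples must be positive")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if len(self.channel_names) != self.n_channels:
            raise ConfigurationError(
                f"{self.n_channels} channels requested but "
                f"{len(self.channel_names)} names given"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ConfigurationError("channel names must be unique")
        missing = set(self.active_channels) - set(self.channel_names)
        if missing:
            raise ConfigurationError(f"active channels not in channel list: {sorted(missing)}")
        nyquist = self.sampling_rate / 2
        for band_name, band in (("control_band", self.control_band),
                                ("alcoholic_band", self.alcoholic_band)):
            lo, hi = band
            if not (0 < lo <= hi < nyquist):
                raise ConfigurationError(
                    f"{band_name}={band} must lie within (0, {nyquist}) Hz"
                )
        if self.artifact_amplitude <= 73.3:
            raise ConfigurationError(
                "artifact_amplitude must exceed the 73.3 µV outlier threshold"
            )
        if self.n_components < 1:
            raise ConfigurationError("n_components must be >= 1")
        if not 0 <= self.artifact_rate <= 1:
            raise ConfigurationError("artifact_rate must be a probability")

    def band_for(self, label: str) -> tuple[float, float]:
        if label == "alcoholic":
            return self.alcoholic_band
        return self.control_band

    def amplitude_for(self, label: str) -> float:
        if label == "alcoholic":
            return self.band_amplitude * self.amplitude_ratio
        return self.band_amplitude


def _band_bins(config: SyntheticConfig, band: tuple[float, float]) -> np.ndarray:
    """DFT bin indices whose frequencies fall inside ``band`` (inclusive)."""
    df = config.sampling_rate / config.n_samples
    lo = int(np.ceil(band[0] / df - 1e-9))
    hi = int(np.floor(band[1] / df + 1e-9))
    bins = np.arange(max(lo, 1), hi + 1)
    if bins.size == 0:
        raise ConfigurationError(
            f"band {band} contains no DFT bin at resolution {df} Hz; "
            "increase n_samples or widen the band"
        )
    return bins


def generate_recording(config: SyntheticConfig, label: str, seed: int) -> Recording:
    """Generate one labeled recording; bit-identical for a fixed (config, seed).

    Active channels receive a sum of ``n_components`` sinusoids with
    random on-grid frequencies inside the class band and random phases,
    plus white Gaussian noise; inactive channels receive noise only.
    Samples selected by a Bernoulli(artifact_rate) draw are replaced by
    +/-``artifact_amplitude`` spikes with random sign.
    """
    if label not in ("control", "alcoholic"):
        raise ConfigurationError(f"label must be 'control' or 'alcoholic', got {label!r}")
    rng = np.random.default_rng(seed)
    band = config.band_for(label)
    amplitude = config.amplitude_for(label)
    bins = _band_bins(config, band)
    t = np.arange(config.n_samples) / config.sampling_rate

    data = np.empty((config.n_channels, config.n_samples))
    active = set(config.active_channels)
    per_component = amplitude / config.n_components
    for row, name in enumerate(config.channel_names):
        signal = np.zeros(config.n_samples)
        if name in active:
            freqs = rng.choice(bins, size=config.n_components) * (
                config.sampling_rate / config.n_samples
            )
            phases = rng.uniform(0, 2 * np.pi, size=config.n_components)
            for f, ph in zip(freqs, phases):
                signal += per_component * np.sin(2 * np.pi * f * t + ph)
        if config.noise_sd > 0:
            signal = signal + rng.normal(0.0, config.noise_sd, size=config.n_samples)
        if config.artifact_rate > 0:
            mask = rng.random(config.n_samples) < config.artifact_rate
            signs = rng.choice([-1.0, 1.0], size=config.n_samples)
            signal = np.where(mask, signs * config.artifact_amplitude, signal)
        data[row] = signal

    return Recording(
        channel_names=list(config.channel_names),
        sampling_rate=config.sampling_rate,
        data=data,
        label=label,
        subject_id=f"sim-{label}-{seed}",
    )


def generate_dataset(config: SyntheticConfig, n_per_class: int, seed: int) -> list[Recording]:
    """Generate a balanced dataset of ``2 * n_per_class`` recordings.

    Per-recording seeds are derived from ``seed`` with a SeedSequence
    spawn, so any subset of the dataset is reproducible independently of
    the rest.
    """
    if n_per_class < 1:
        raise ConfigurationError("n_per_class must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(2 * n_per_class)
    recordings: list[Recording] = []
    for i in range(n_per_class):
        for j, label in enumerate(("control", "alcoholic")):
            rec_seed = int(child_seeds[2 * i + j] % (2**31))
            rec = generate_recording(config, label, rec_seed)
            rec.subject_id = f"sim-{label}-{i:03d}"
            recordings.append(rec)
    return recordings
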