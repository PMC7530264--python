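"""Reading and writing multichannel EEG recordings as plain text.

Two dialects are supported:

* a CSV matrix dialect: one row per channel, first field the channel
  name, remaining fields the samples in µV;
* a UCI-style event dialect: ``#``-prefixed comment lines plus
  whitespace-delimited 4-field records ``trial channel sample value``,
  as distributed by the public UCI KDD EEG archive. Trials are
  concatenated along time in ascending trial order, which is how a
  256 samples/s, ~1 s-per-trial acquisition reaches the 1,024-sample
  time axis the imaging stage expects.

Plus a manifest CSV (``subject_id,label,path``) tying recordings to
class labels.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import ConfigurationError, ParseError, Recording, VALID_LABELS


@dataclass
class ManifestEntry:
    subject_id: str
    label: str
    path: Path


@dataclass
class RecordingManifest:
    """An ordered list of (subject_id, label, path) entries."""

    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        paths = [str(e.path) for e in self.entries]
        if len(set(paths)) != len(paths):
            raise ConfigurationError("manifest paths must be unique")
        for e in self.entries:
            if e.label not in VALID_LABELS:
                raise ConfigurationError(f"manifest label {e.label!r} not in {VALID_LABELS}")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def read_csv_recording(
    path: str | Path,
    sampling_rate: float = 256.0,
    label: str = "unknown",
    subject_id: str | None = None,
) -> Recording:
    """Read a CSV matrix recording (channel name + samples per row)."""
    path = Path(path)
    names: list[str] = []
    rows: list[list[float]] = []
    with path.open(newline="") as fh:
        for lineno, record in enumerate(csv.reader(fh), start=1):
            if not record or (len(record) == 1 and not record[0].strip()):
                continue
            name, *samples = record
            if not samples:
                raise ParseError(f"{path}:{lineno}: channel {name!r} has no samples")
            try:
                values = [float(v) for v in samples]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric sample ({exc})") from None
            if rows and len(values) != len(rows[0]):
                raise ParseError(
                    f"{path}:{lineno}: ragged row: {len(values)} samples, "
                    f"expected {len(rows[0])}"
                )
            names.append(name.strip())
            rows.append(values)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    return Recording(
        channel_names=names,
        sampling_rate=sampling_rate,
        data=np.array(rows),
        label=label,
        subject_id=subject_id if subject_id is not None else path.stem,
    )


def write_csv_recording(recording: Recording, path: str | Path) -> None:
    """Write a recording in the CSV matrix dialect (full float precision)."""
    if recording.n_samples == 0:
        raise ConfigurationError("refusing to write a 0-sample recording")
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        for name, row in zip(recording.channel_names, recording.data):
            writer.writerow([name] + [repr(float(v)) for v in row])


def read_uci_text(
    path: str | Path,
    sampling_rate: float = 256.0,
    label: str = "unknown",
    subject_id: str | None = None,
) -> Recording:
    """Read a UCI-style trial/channel/sample/value text file.

    Channels are assembled in sample-index order within each trial and
    trials concatenated in ascending trial order. Row order of the
    resulting matrix is lexicographic by channel name, so parsing is
    insensitive to the order of the record lines.
    """
    path = Path(path)
    # values[(channel, trial)][sample] = µV
    values: dict[tuple[str, int], dict[int, float]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(
                    f"{path}:{lineno}: expected 4 fields (trial channel sample value), "
                    f"got {len(fields)}"
                )
            try:
                trial = int(fields[0])
                sample = int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            channel = fields[1]
            key = (channel, trial)
            bucket = values.setdefault(key, {})
            if sample in bucket:
                raise ParseError(
                    f"{path}:{lineno}: duplicate record for trial {trial}, "
                    f"channel {channel}, sample {sample}"
                )
            bucket[sample] = value
    if not values:
        raise ParseError(f"{path}: no records (comment-only or empty file)")

    channels = sorted({c for c, _ in values})
    trials = sorted({t for _, t in values})
    per_trial_len: dict[int, int] = {}
    for trial in trials:
        lengths = set()
        for channel in channels:
            bucket = values.get((channel, trial))
            if bucket is None:
                raise ParseError(
                    f"{path}: channel {channel} missing from trial {trial}"
                )
            idx = sorted(bucket)
            expected = list(range(len(idx)))
            if idx != expected:
                gaps = sorted(set(expected) - set(idx))[:10]
                raise ParseError(
                    f"{path}: trial {trial}, channel {channel}: sample indices "
                    f"not contiguous from 0; missing {gaps}"
                )
            lengths.add(len(idx))
        if len(lengths) != 1:
            raise ParseError(f"{path}: trial {trial} has ragged channel lengths {sorted(lengths)}")
        per_trial_len[trial] = lengths.pop()

    data = np.empty((len(channels), sum(per_trial_len.values())))
    for row, channel in enumerate(channels):
        offset = 0
        for trial in trials:
            bucket = values[(channel, trial)]
            n = per_trial_len[trial]
            data[row, offset:offset + n] = [bucket[i] for i in range(n)]
            offset += n
    return Recording(
        channel_names=channels,
        sampling_rate=sampling_rate,
        data=data,
        label=label,
        subject_id=subject_id if subject_id is not None else path.stem,
    )


def read_manifest(path: str | Path) -> RecordingManifest:
    """Read a ``subject_id,label,path`` manifest CSV (relative paths resolve
    against the manifest's directory)."""
    path = Path(path)
    entries: list[ManifestEntry] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        for lineno, record in enumerate(reader, start=1):
            if not record or (len(record) == 1 and not record[0].strip()):
                continue
            if lineno == 1 and [f.strip().lower() for f in record[:2]] == ["subject_id", "label"]:
                continue
            if len(record) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 fields, got {len(record)}")
            subject_id, label, rec_path = (f.strip() for f in record)
            p = Path(rec_path)
            if not p.is_absolute():
                p = path.parent / p
            entries.append(ManifestEntry(subject_id=subject_id, label=label, path=p))
    if not entries:
        raise ParseError(f"{path}: empty manifest")
    return RecordingManifest(entries=entries)


def write_manifest(manifest: RecordingManifest, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "label", "path"])
        for e in manifest.entries:
            writer.writerow([e.subject_id, e.label, str(e.path)])
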