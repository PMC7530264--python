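"""End-to-end orchestration: manifest -> conditioning -> image -> features -> metrics.

``run_pipeline`` wires the stages together and wraps stage failures in
:class:`~eegmap.core.PipelineStageError` so a broken input names the
stage that rejected it. ``features_from_recordings`` is the in-memory
variant used when recordings are generated rather than read from disk.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .core import EEGMapError, FeatureVector, PipelineStageError, Recording
from .evaluation import EvalResult, HyperparamSpace, evaluate
from .imaging import compose_heatmap
from .io import RecordingManifest, read_csv_recording, read_manifest
from .preprocess import PipelineConfig, preprocess_recording
from .texture import extract_traditional

TRADITIONAL_EXTRACTORS = ("glcm", "lbp", "hu", "all")


def _stage(stage_name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineStageError:
        raise
    except (EEGMapError, OSError) as exc:
        raise PipelineStageError(stage_name, str(exc)) from exc


def recording_to_image(recording: Recording, config: PipelineConfig | None = None):
    """Conditioning + composition for a single recording."""
    config = config or PipelineConfig()
    quantized = _stage("preprocess", preprocess_recording, recording, config)
    return _stage("imaging", compose_heatmap, quantized, config)


def features_from_recordings(
    recordings: Sequence[Recording],
    config: PipelineConfig | None = None,
    extractor: str | Callable[[object], FeatureVector] = "lbp",
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Transform recordings into a (features, labels, names) triple.

    ``extractor`` is a traditional extractor id ("glcm", "lbp", "hu",
    "all") or any callable mapping a heat-map image to a FeatureVector
    (e.g. an injected deep backbone via ``extract_deep``).
    """
    config = config or PipelineConfig()
    if isinstance(extractor, str):
        if extractor not in TRADITIONAL_EXTRACTORS:
            raise PipelineStageError(
                "features",
                f"unknown extractor {extractor!r}; choose from {TRADITIONAL_EXTRACTORS} "
                "or pass a callable",
            )
        extract = lambda img: extract_traditional(img, which=extractor)
    else:
        extract = extractor
    rows, labels, names = [], [], None
    for rec in recordings:
        image = recording_to_image(rec, config)
        fv = _stage("features", extract, image)
        if names is None:
            names = fv.names
        rows.append(fv.values)
        labels.append(rec.label)
    return np.vstack(rows), np.asarray(labels), list(names or [])


def run_pipeline(
    manifest: str | Path | RecordingManifest,
    config: PipelineConfig | None = None,
    extractor: str | Callable[[object], FeatureVector] = "lbp",
    family: str = "rf",
    seed: int = 0,
    sampling_rate: float = 256.0,
    n_splits: int = 10,
    n_iter: int = 20,
    inner_folds: int = 10,
    space: HyperparamSpace | None = None,
    report_path: str | Path | None = None,
) -> EvalResult:
    """Full run: read the manifest, build features, evaluate one family.

    Writes a machine-readable JSON report (configs, seeds, per-split
    metrics, chosen hyperparameters) to ``report_path`` when given.
    """
    config = config or PipelineConfig()
    if isinstance(manifest, (str, Path)):
        manifest = _stage("eeg_io", read_manifest, manifest)
    recordings = [
        _stage("eeg_io", read_csv_recording, e.path, sampling_rate, e.label, e.subject_id)
        for e in manifest
    ]
    X, y, feature_names = features_from_recordings(recordings, config, extractor)
    result = _stage(
        "classify_eval", evaluate, X, y, family,
        n_splits=n_splits, seed=seed, n_iter=n_iter, inner_folds=inner_folds,
        space=space,
    )
    if report_path is not None:
        extractor_id = extractor if isinstance(extractor, str) else getattr(
            extractor, "__name__", "custom"
        )
        report = {
            "seed": seed,
            "sampling_rate": sampling_rate,
            "pipeline_config": config.to_dict(),
            "extractor": extractor_id,
            "n_features": len(feature_names),
            "n_recordings": len(recordings),
            "results": {family: result.to_dict()},
        }
        Path(report_path).write_text(json.dumps(report, indent=2))
    return result
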