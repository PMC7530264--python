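"""Simulate a two-class EEG dataset and render one recording as a heat map.

The generator emulates the structure the pipeline feeds on: 64 channels
at 256 Hz, with the 11 high-variance channels carrying a low-frequency
(control, 1-7 Hz) or high-frequency (alcoholic, 20-50 Hz) band signal,
plus occasional +/-90 µV movement artifacts.
"""

from pathlib import Path

from eegmap import (
    PipelineConfig,
    SyntheticConfig,
    generate_dataset,
    recording_to_image,
    write_png,
)

out_dir = Path("scratch")
out_dir.mkdir(exist_ok=True)

recordings = generate_dataset(SyntheticConfig(), n_per_class=2, seed=0)
print(f"generated {len(recordings)} recordings "
      f"({recordings[0].n_channels} channels x {recordings[0].n_samples} samples)")

for rec in recordings[:2]:
    image = recording_to_image(rec, PipelineConfig())
    path = out_dir / f"{rec.subject_id}.png"
    write_png(image, path)
    print(f"{rec.subject_id} ({rec.label}): image {image.shape[0]} x {image.shape[1]} "
          f"-> {path}")

# The 1024 x 352 geometry is the default contract: 1024 time samples down
# the rows, 11 selected channels x 32-pixel blocks across the columns.
# A control-class image shows smooth vertical bands (slow oscillations);
# an alcoholic-class image shows rough, rapidly alternating texture.
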