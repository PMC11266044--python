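"""Simulate a small acquisition and run both workflows end to end.

Writes a synthetic 3-section brain (2x2 grid of 128 px tiles, 2 channels,
vignetted), stitches every section, assembles the volume products, and
prints the run manifest highlights.  The viewer URL at the end points a
Neuroglancer-style viewer at the OME-Zarr store this run wrote.
"""

import tempfile
from pathlib import Path

from braintile.fixtures import (VignetteModel, make_vignette_gain,
                                write_fixture_tree)
from braintile.metadata_io import BrainVolumeMetadata
from braintile.pipeline import (PipelineConfig, run_stitch_pipeline,
                                run_volume_pipeline)

work = Path(tempfile.mkdtemp(prefix="braintile_demo_"))
meta = BrainVolumeMetadata(
    brain_id="B0001", n_sections=3, tiles_per_row=2, tiles_per_col=2,
    tile_height_px=128, tile_width_px=128, n_channels=2,
    channel_names=("red", "green"), nominal_overlap_px=32)
gain = make_vignette_gain(VignetteModel(128, 128, center_gain=1.0,
                                        edge_gain=0.6))
write_fixture_tree(work / "in", meta, gain=gain, seed=0)
print(f"acquisition written under {work / 'in' / 'B0001'}")

cfg = PipelineConfig(input_root=str(work / "in"), output_root=str(work / "out"),
                     brain_id="B0001", workers=2, downsample_targets_um=(),
                     n_levels=2)
stitch = run_stitch_pipeline(cfg)
print(f"stitched {len(stitch.sections)} sections, "
      f"{sum(s['missing_tiles'] for s in stitch.sections.values())} missing "
      f"tiles, estimated steps saved to {stitch.outputs['translation_params']}")

vol = run_volume_pipeline(cfg)
print("volume products (z extent = number of sections, spacing from metadata):")
for ch, outs in vol.outputs.items():
    print(f"  {ch}: {outs['nifti']}")
print("viewer URL:", vol.outputs["red"]["viewer_url"][:90], "...")
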