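import numpy as np
import pytest

from braintile.fixtures import (VignetteModel, make_vignette_gain,
                                write_fixture_tree)
from braintile.metadata_io import BrainVolumeMetadata


@pytest.fixture
def small_meta() -> BrainVolumeMetadata:
    """2 sections of a 2x2 grid, 2 channels, 128 px tiles, 32 px overlap."""
    return BrainVolumeMetadata(
        brain_id="B0001", n_sections=2, tiles_per_row=2, tiles_per_col=2,
        tile_height_px=128, tile_width_px=128, n_channels=2,
        channel_names=("red", "green"), nominal_overlap_px=32)


@pytest.fixture
def fixture_tree(tmp_path, small_meta):
    """A complete small on-disk acquisition plus its ground truth."""
    truth = write_fixture_tree(tmp_path, small_meta, seed=11)
    return tmp_path, small_meta, truth


@pytest.fixture
def vignetted_tree(tmp_path):
    """Vignetted acquisition with enough sections that the per-channel
    profiles average the tissue texture out (20 sections x 4 tiles; the
    real acquisition averages thousands of tiles per channel)."""
    meta = BrainVolumeMetadata(
        brain_id="B0001", n_sections=20, tiles_per_row=2, tiles_per_col=2,
        tile_height_px=128, tile_width_px=128, n_channels=2,
        channel_names=("red", "green"), nominal_overlap_px=32)
    gain = make_vignette_gain(VignetteModel(128, 128, 1.0, 0.6))
    truth = write_fixture_tree(tmp_path, meta, gain=gain, seed=11)
    return tmp_path, meta, truth, gain
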