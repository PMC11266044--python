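"""Flat-field (brightness) normalization.

Lens vignetting makes tile centres brighter than tile edges.  Averaging many
tiles of one colour channel washes out the tissue and leaves the optical
gain pattern: we call that average the channel's *profile*.  Dividing every
tile pixel-by-pixel by the profile flattens the illumination, so stitched
sections show no tile-shaped brightness grid.

Profiles are computed per channel, by default over all tiles of the brain
(tiles of the same grid position in different sections average out labelled
cells); a per-section scope is available.  Missing-tile placeholders (all
zeros) are excluded from the average.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import tifffile

from .metadata_io import Tile

__all__ = ["Profile", "compute_profile", "normalize_tile",
           "save_profile", "load_profile"]


@dataclass
class Profile:
    """Per-channel average tile used as a flat-field divisor."""

    channel: str
    pixels: np.ndarray          # 2D float64, tile-shaped, >= 0
    n_tiles_averaged: int
    epsilon: float              # division floor

    @property
    def mean(self) -> float:
        return float(self.pixels.mean())


def _epsilon_for(pixels: np.ndarray) -> float:
    # floor prevents blow-up at dead pixels without biasing bright areas
    return max(1e-6, 1e-3 * float(pixels.mean()))


def compute_profile(tiles: Iterable[Tile | np.ndarray],
                    channel: str = "") -> Profile:
    """Per-pixel arithmetic mean over the given tiles of one channel.

    Tiles flagged missing (or all-zero placeholders) are excluded.  Raises
    ``ValueError`` if no tile remains.
    """
    acc: np.ndarray | None = None
    n = 0
    for t in tiles:
        if isinstance(t, Tile):
            if t.record.missing:
                continue
            px = t.pixels
            channel = channel or t.record.channel
        else:
            px = t
        px = np.asarray(px, dtype=np.float64)
        if not px.any():        # all-zero placeholder
            continue
        if acc is None:
            acc = np.zeros_like(px)
        elif acc.shape != px.shape:
            raise ValueError(f"tile shape {px.shape} != profile shape {acc.shape}")
        acc += px
        n += 1
    if acc is None or n == 0:
        raise ValueError("no tiles to average")
    pixels = acc / n
    return Profile(channel=channel, pixels=pixels, n_tiles_averaged=n,
                   epsilon=_epsilon_for(pixels))


def normalize_tile(tile: Tile | np.ndarray, profile: Profile) -> np.ndarray:
    """Divide a tile pixel-by-pixel by its channel profile.

    Returns a float64 image.  A tile equal to its profile maps to all ones;
    values above 1 mean brighter-than-average (labelled cells) and are kept —
    there is no clamping.  All-zero placeholder tiles map to all zeros.
    """
    if isinstance(tile, Tile):
        if tile.record.channel and profile.channel and \
                tile.record.channel != profile.channel:
            raise ValueError(
                f"channel mismatch: tile {tile.record.channel!r} vs "
                f"profile {profile.channel!r}")
        px = tile.pixels
    else:
        px = tile
    px = np.asarray(px, dtype=np.float64)
    if px.shape != profile.pixels.shape:
        raise ValueError(
            f"tile shape {px.shape} != profile shape {profile.pixels.shape}")
    return px / np.maximum(profile.pixels, profile.epsilon)


def save_profile(profile: Profile, path: str | Path) -> None:
    """Write the profile as 32-bit float TIFF plus a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, profile.pixels.astype(np.float32))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "channel": profile.channel,
        "n_tiles_averaged": profile.n_tiles_averaged,
        "epsilon": profile.epsilon,
    }, indent=2))


def load_profile(path: str | Path) -> Profile:
    path = Path(path)
    pixels = tifffile.imread(path).astype(np.float64)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return Profile(channel=meta["channel"], pixels=pixels,
                   n_tiles_averaged=meta["n_tiles_averaged"],
                   epsilon=meta["epsilon"])
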