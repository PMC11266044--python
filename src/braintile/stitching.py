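"""Canvas placement and seamless blending of corrected tiles.

Tile (r, c) lands at ``(margin + r*step_y + c*dy_drift,
margin + c*step_x + r*dx_drift)`` on a blank canvas whose dimensions come
from the section metadata.  Overlaps are resolved without trimming: every
covering tile contributes with a weight, and the output pixel is the
weighted mean.  With *feather* blending the weight ramps linearly from the
tile edge to the overlap depth, which removes seam steps; *mean* blending
(uniform weights) is the plain average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import tifffile

from .metadata_io import SectionMetadata
from .translation import TranslationParams

__all__ = ["TilePlacement", "SectionImage", "compute_tile_positions",
           "stitch_section", "write_section", "full_scale_translation_params"]


@dataclass(frozen=True)
class TilePlacement:
    """Canvas coordinates of one tile's top-left pixel."""

    row: int
    col: int
    y0: int
    x0: int


@dataclass
class SectionImage:
    """One stitched section canvas for one channel."""

    pixels: np.ndarray
    section_index: int = 0
    channel: str = ""
    provenance: dict | None = None


def full_scale_translation_params() -> TranslationParams:
    """The step geometry that reproduces the full-scale printed canvas:
    steps (y=788, x=800) px with zero drift, which with margin 4 and an
    11 x 14 grid of 832 px tiles gives an 8,716 x 11,236 px section."""
    return TranslationParams(step_x_px=800, step_y_px=788)


def compute_tile_positions(section_meta: SectionMetadata,
                           params: TranslationParams,
                           tile_shape: tuple[int, int],
                           ) -> list[TilePlacement]:
    """Compute every tile's canvas position from the translation parameters.

    Validates that the canvas arithmetic is consistent
    (``margin + (n-1)*step + tile`` per axis; a mismatch warns, trusting the
    metadata) and that every placement fits the canvas (a violation raises,
    showing the arithmetic).
    """
    rows, cols = section_meta.tiles_per_col, section_meta.tiles_per_row
    th, tw = tile_shape
    m = section_meta.margin_px
    expected_h = m + (rows - 1) * params.step_y_px + th
    expected_w = m + (cols - 1) * params.step_x_px + tw
    if (expected_h, expected_w) != (section_meta.canvas_height_px,
                                    section_meta.canvas_width_px):
        warnings.warn(
            f"canvas {section_meta.canvas_height_px}x{section_meta.canvas_width_px} "
            f"differs from margin + (n-1)*step + tile = {expected_h}x{expected_w}; "
            f"trusting metadata", stacklevel=2)
    placements = []
    for r in range(rows):
        for c in range(cols):
            y0 = m + r * params.step_y_px + c * params.dy_at_horizontal_px
            x0 = m + c * params.step_x_px + r * params.dx_at_vertical_px
            if y0 < 0 or x0 < 0 or y0 + th > section_meta.canvas_height_px \
                    or x0 + tw > section_meta.canvas_width_px:
                raise ValueError(
                    f"tile ({r},{c}) at ({y0},{x0}) + {tile_shape} exceeds canvas "
                    f"{section_meta.canvas_height_px}x{section_meta.canvas_width_px}: "
                    f"y0 = {m} + {r}*{params.step_y_px} + {c}*"
                    f"{params.dy_at_horizontal_px}, x0 = {m} + {c}*"
                    f"{params.step_x_px} + {r}*{params.dx_at_vertical_px}")
            placements.append(TilePlacement(row=r, col=c, y0=y0, x0=x0))
    return placements


def _feather_weights(tile_shape: tuple[int, int], depth: int) -> np.ndarray:
    """Separable linear ramp: per axis the weight climbs from 1/depth at edge
    pixels to 1 at ``depth`` pixels in, and the tile weight is the product of
    the two axis ramps.  Separability makes the perpendicular factor cancel
    between tiles sharing an edge, so the blend ramps cleanly across every
    overlap; weights are strictly positive so single-coverage pixels are
    preserved exactly."""
    th, tw = tile_shape
    d = max(depth, 1)
    ry = np.minimum((np.minimum(np.arange(th), np.arange(th)[::-1]) + 1) / d, 1.0)
    rx = np.minimum((np.minimum(np.arange(tw), np.arange(tw)[::-1]) + 1) / d, 1.0)
    return np.outer(ry, rx)


def _default_feather_depth(placements: list[TilePlacement],
                           tile_shape: tuple[int, int]) -> int:
    """Smallest positive overlap between adjacent placements, else 1."""
    ys = sorted({p.y0 for p in placements})
    xs = sorted({p.x0 for p in placements})
    cands = []
    if len(ys) > 1:
        cands.append(tile_shape[0] - min(np.diff(ys)))
    if len(xs) > 1:
        cands.append(tile_shape[1] - min(np.diff(xs)))
    depth = int(min(cands)) if cands else 1
    return max(depth, 1)


def stitch_section(tiles: list[np.ndarray], placements: list[TilePlacement],
                   canvas_shape: tuple[int, int], blend: str = "feather",
                   feather_depth: int | None = None) -> np.ndarray:
    """Blend tiles onto the canvas; returns a float64 canvas.

    Every output pixel is the weight-normalized mean of the tiles covering it
    (convex combination, so blended values never leave the covering tiles'
    range); pixels covered by a single tile equal that tile's value exactly;
    uncovered pixels are 0.  All-zero placeholder tiles participate with
    their zeros.
    """
    if len(tiles) != len(placements):
        raise ValueError(f"{len(tiles)} tiles but {len(placements)} placements")
    if blend not in ("feather", "mean"):
        raise ValueError(f"blend must be feather|mean, got {blend!r}")
    if not tiles:
        raise ValueError("no tiles to stitch")
    tile_shape = tiles[0].shape
    acc = np.zeros(canvas_shape, dtype=np.float64)
    wacc = np.zeros(canvas_shape, dtype=np.float64)
    if blend == "feather":
        depth = feather_depth or _default_feather_depth(placements, tile_shape)
        w = _feather_weights(tile_shape, depth)
    else:
        w = np.ones(tile_shape)
    for tile, p in zip(tiles, placements):
        if tile.shape != tile_shape:
            raise ValueError("all tiles must share a shape")
        sl = (slice(p.y0, p.y0 + tile_shape[0]), slice(p.x0, p.x0 + tile_shape[1]))
        acc[sl] += w * np.asarray(tile, dtype=np.float64)
        wacc[sl] += w
    out = np.zeros(canvas_shape, dtype=np.float64)
    covered = wacc > 0
    out[covered] = acc[covered] / wacc[covered]
    return out


def write_section(image: SectionImage | np.ndarray, path,
                  rescale: float = 1.0, dtype=np.uint16) -> int:
    """Write a stitched section as TIFF after rescale; returns the number of
    pixels clipped at the dtype limits."""
    pixels = image.pixels if isinstance(image, SectionImage) else image
    scaled = np.asarray(pixels, dtype=np.float64) * rescale
    info = np.iinfo(dtype)
    clipped = int(np.count_nonzero((scaled < info.min) | (scaled > info.max)))
    out = np.clip(np.round(scaled), info.min, info.max).astype(dtype)
    tifffile.imwrite(path, out)
    return clipped
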