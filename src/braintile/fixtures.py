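"""Synthetic acquisitions with known ground truth.

Everything the pipeline consumes — tissue-like phantom sections, vignetting
gain fields, smooth lens-warp fields, calibration-grid target images, and
complete on-disk tile trees — can be generated here deterministically from a
seed, so every stage is testable against an analytic truth without any
downloaded data.

Conventions shared with the correction modules: images are (row, col) arrays,
y-down; warps are applied by inverse mapping with bilinear interpolation and
edge-replicated borders.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .metadata_io import (
    BRAIN_METADATA_FILENAME,
    SECTION_METADATA_FILENAME,
    BrainVolumeMetadata,
    SectionMetadata,
    section_dirname,
    serialize_brain_metadata,
    serialize_section_metadata,
    tile_filename,
)

__all__ = [
    "PhantomSpec",
    "VignetteModel",
    "SyntheticWarp",
    "generate_phantom_section",
    "phantom_cell_count",
    "make_vignette_gain",
    "warp_image",
    "warp_points",
    "slice_into_tiles",
    "generate_grid_image",
    "write_fixture_tree",
    "full_scale_brain_metadata",
]

MAX_U16 = 65535.0


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a tissue-like section: bright soft-edged cells on background.

    ``cell_density`` is cells per megapixel.  The sampling procedure is fixed
    and documented so tests can reproduce it independently: with
    ``rng = np.random.default_rng(seed)`` the first draw is
    ``rng.poisson(cell_density * height_px * width_px / 1e6)`` (the cell
    count), followed by ``rng.uniform`` cell centres (y then x, vectorised),
    ``rng.uniform(0.5, 1.0)`` per-cell amplitude factors, and finally
    ``rng.normal`` pixel noise.
    """

    height_px: int
    width_px: int
    cell_density: float = 40.0
    cell_radius_px: float = 6.0
    background_level: float = 400.0
    cell_amplitude: float = 2500.0
    noise_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px <= 0 or self.width_px <= 0:
            raise ValueError("phantom dimensions must be positive")
        if self.cell_density < 0 or self.cell_radius_px <= 0:
            raise ValueError("cell_density must be >= 0 and cell_radius_px > 0")
        if not (0 <= self.background_level <= MAX_U16):
            raise ValueError("background_level outside [0, 65535]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def phantom_cell_count(spec: PhantomSpec) -> int:
    """The cell count :func:`generate_phantom_section` will draw for ``spec``.

    Re-runs the documented first step of the sampling procedure.
    """
    rng = np.random.default_rng(spec.seed)
    return int(rng.poisson(spec.cell_density * spec.height_px * spec.width_px / 1e6))


def generate_phantom_section(spec: PhantomSpec) -> np.ndarray:
    """Render a phantom section as float32, deterministic in ``spec.seed``.

    Cells are Gaussian-profile disks (sigma = radius / 2) of amplitude
    ``cell_amplitude`` scaled by a per-cell uniform factor in [0.5, 1.0];
    Gaussian noise of SD ``noise_sd`` is added and the result clipped to
    [0, 65535].
    """
    h, w = spec.height_px, spec.width_px
    rng = np.random.default_rng(spec.seed)
    n_cells = int(rng.poisson(spec.cell_density * h * w / 1e6))
    img = np.full((h, w), spec.background_level, dtype=np.float64)
    if n_cells > 0:
        ys = rng.uniform(0, h, n_cells)
        xs = rng.uniform(0, w, n_cells)
        amps = spec.cell_amplitude * rng.uniform(0.5, 1.0, n_cells)
        sigma = spec.cell_radius_px / 2.0
        half = int(np.ceil(3.0 * sigma))
        for cy, cx, a in zip(ys, xs, amps):
            y0, y1 = max(0, int(cy) - half), min(h, int(cy) + half + 1)
            x0, x1 = max(0, int(cx) - half), min(w, int(cx) + half + 1)
            yy = np.arange(y0, y1)[:, None] - cy
            xx = np.arange(x0, x1)[None, :] - cx
            img[y0:y1, x0:x1] += a * np.exp(-(yy * yy + xx * xx) / (2.0 * sigma * sigma))
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=(h, w))
    return np.clip(img, 0.0, MAX_U16).astype(np.float32)


# ---------------------------------------------------------------------------
# vignetting

@dataclass(frozen=True)
class VignetteModel:
    """Radial gain field: brightest at the tile centre, dimmest at corners."""

    tile_height_px: int
    tile_width_px: int
    center_gain: float = 1.0
    edge_gain: float = 0.6
    profile_shape: str = "radial_quadratic"

    def __post_init__(self) -> None:
        if self.tile_height_px <= 0 or self.tile_width_px <= 0:
            raise ValueError("tile dimensions must be positive")
        if not (0.0 < self.edge_gain <= self.center_gain <= 1.0):
            raise ValueError(
                f"require 0 < edge_gain <= center_gain <= 1, got "
                f"edge={self.edge_gain}, center={self.center_gain}")
        if self.profile_shape not in ("radial_quadratic", "radial_gaussian"):
            raise ValueError(f"unknown profile_shape {self.profile_shape!r}")


def make_vignette_gain(model: VignetteModel) -> np.ndarray:
    """Gain image in (0, 1]: ``center_gain`` at the centre, ``edge_gain`` at
    the farthest corner, radially non-increasing in between."""
    h, w = model.tile_height_px, model.tile_width_px
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    rmax2 = r2[0, 0]  # corners are equidistant from the centre
    cg, eg = model.center_gain, model.edge_gain
    if rmax2 == 0 or cg == eg:
        return np.full((h, w), cg, dtype=np.float64)
    if model.profile_shape == "radial_quadratic":
        gain = cg - (cg - eg) * (r2 / rmax2)
    else:  # radial_gaussian: cg * exp(-k r^2) with k fixed so corners hit eg
        gain = cg * np.exp(-(r2 / rmax2) * np.log(cg / eg))
    return gain


# ---------------------------------------------------------------------------
# smooth synthetic warps

@dataclass(frozen=True)
class SyntheticWarp:
    """Smooth random displacement field standing in for lens distortion.

    The field is white noise smoothed with a Gaussian of scale
    ``smoothness_scale_px``, de-meaned, then rescaled so the maximum
    displacement magnitude equals ``amplitude_px``.  A point at ``p`` in the
    undistorted scene appears at ``p + displacement(p)`` in the warped image
    (forward convention); images are warped by iteratively inverting that map.
    """

    amplitude_px: float
    smoothness_scale_px: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_px < 0:
            raise ValueError("amplitude_px must be >= 0")
        if self.smoothness_scale_px <= 0:
            raise ValueError("smoothness_scale_px must be positive")

    def displacement(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Dense (dy, dx) forward-displacement arrays for ``shape``."""
        h, w = shape
        rng = np.random.default_rng(self.seed)
        if self.amplitude_px == 0:
            z = np.zeros((h, w))
            return z, z.copy()
        dy = ndimage.gaussian_filter(rng.standard_normal((h, w)),
                                     self.smoothness_scale_px, mode="reflect")
        dx = ndimage.gaussian_filter(rng.standard_normal((h, w)),
                                     self.smoothness_scale_px, mode="reflect")
        dy -= dy.mean()
        dx -= dx.mean()
        mag = np.sqrt(dy * dy + dx * dx).max()
        if mag > 0:
            dy *= self.amplitude_px / mag
            dx *= self.amplitude_px / mag
        return dy, dx


def warp_points(points: np.ndarray, warp: SyntheticWarp,
                shape: tuple[int, int]) -> np.ndarray:
    """Forward-warp (..., 2) (y, x) points: ``p -> p + d(p)``."""
    dy, dx = warp.displacement(shape)
    pts = np.asarray(points, dtype=np.float64)
    coords = [pts[..., 0].ravel(), pts[..., 1].ravel()]
    off_y = ndimage.map_coordinates(dy, coords, order=1, mode="nearest")
    off_x = ndimage.map_coordinates(dx, coords, order=1, mode="nearest")
    out = pts.copy()
    out[..., 0] += off_y.reshape(pts[..., 0].shape)
    out[..., 1] += off_x.reshape(pts[..., 1].shape)
    return out


def warp_image(image: np.ndarray, warp: SyntheticWarp,
               n_iter: int = 8) -> np.ndarray:
    """Warp an image under the forward map ``T(p) = p + d(p)``.

    The inverse map is found by fixed-point iteration ``p <- q - d(p)``
    (converges because the field is smooth and small relative to its
    smoothness scale), then the image is resampled bilinearly with
    edge-replicated borders.
    """
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape
    dy, dx = warp.displacement((h, w))
    base = np.mgrid[0:h, 0:w].astype(np.float64)
    p = base.copy()
    for _ in range(n_iter):
        oy = ndimage.map_coordinates(dy, p, order=1, mode="nearest")
        ox = ndimage.map_coordinates(dx, p, order=1, mode="nearest")
        p[0] = base[0] - oy
        p[1] = base[1] - ox
    return ndimage.map_coordinates(img, p, order=1, mode="nearest")


# ---------------------------------------------------------------------------
# tiling fixture

def slice_into_tiles(section: np.ndarray, rows: int, cols: int,
                     step_y_px: int, step_x_px: int,
                     tile_h: int, tile_w: int,
                     gain: np.ndarray | None = None,
                     warp: SyntheticWarp | None = None,
                     ) -> tuple[list[np.ndarray], np.ndarray]:
    """Cut an overlapping tile grid out of a section.

    Tile (r, c) is the section crop at (r*step_y, c*step_x) of shape
    (tile_h, tile_w), multiplied by ``gain`` (vignetting) and then warped
    (lens distortion), in acquisition order.  Returns the tiles
    (row-major list) and the exact ground-truth top-left positions as an
    (rows*cols, 2) integer array.
    """
    h, w = section.shape
    if rows < 1 or cols < 1:
        raise ValueError("layout must contain at least one tile")
    if step_y_px >= tile_h and rows > 1 or step_x_px >= tile_w and cols > 1:
        raise ValueError("steps must be smaller than the tile so neighbours overlap")
    if (rows - 1) * step_y_px + tile_h > h or (cols - 1) * step_x_px + tile_w > w:
        raise ValueError(
            f"layout {rows}x{cols} with steps ({step_y_px},{step_x_px}) and tile "
            f"({tile_h},{tile_w}) exceeds section shape {section.shape}")
    if gain is not None and gain.shape != (tile_h, tile_w):
        raise ValueError("gain shape must equal the tile shape")
    tiles: list[np.ndarray] = []
    positions = np.empty((rows * cols, 2), dtype=np.int64)
    for r in range(rows):
        for c in range(cols):
            y0, x0 = r * step_y_px, c * step_x_px
            tile = np.asarray(section[y0:y0 + tile_h, x0:x0 + tile_w],
                              dtype=np.float64).copy()
            if gain is not None:
                tile *= gain
            if warp is not None:
                tile = warp_image(tile, warp)
            tiles.append(tile)
            positions[r * cols + c] = (y0, x0)
    return tiles, positions


# ---------------------------------------------------------------------------
# calibration grid target

def generate_grid_image(pitch_px: float, bar_px: float,
                        size: tuple[int, int],
                        warp: SyntheticWarp | None = None,
                        noise_sd: float = 0.0,
                        hole_level: float = 3000.0,
                        bar_level: float = 300.0,
                        blur_sigma: float = 0.7,
                        seed: int = 0,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Render an EM-mesh-grid calibration target and its true corner lattice.

    Dark bars of width ``bar_px`` are centred on every multiple of
    ``pitch_px`` in both axes; holes are bright.  Cell corners sit on the
    lattice ``(i*pitch, j*pitch)``.  Returns ``(image, corners)`` where
    ``corners`` has shape (n_i, n_j, 2) holding (y, x) for every lattice node
    inside the image — forward-warped when ``warp`` is given, so they are the
    exact truth for the rendered image.
    """
    if bar_px >= pitch_px:
        raise ValueError(f"bar_px ({bar_px}) must be < pitch_px ({pitch_px})")
    h, w = size
    # 4x supersampled area coverage: bar/hole pixel mass matches the
    # continuous geometry exactly, and hole centroids stay on the lattice
    ss = 4
    sub = (np.arange(ss) + 0.5) / ss - 0.5

    def axis_bar_cov(n: int) -> np.ndarray:
        coords = np.arange(n)[:, None] + sub[None, :]
        dist = np.abs(coords - np.round(coords / pitch_px) * pitch_px)
        return (dist < bar_px / 2.0).mean(axis=1)

    hole_y = 1.0 - axis_bar_cov(h)
    hole_x = 1.0 - axis_bar_cov(w)
    hole_cov = np.outer(hole_y, hole_x)
    img = bar_level + (hole_level - bar_level) * hole_cov
    if blur_sigma > 0:
        img = ndimage.gaussian_filter(img, blur_sigma, mode="nearest")
    iy = np.arange(0, int(np.floor((h - 1) / pitch_px)) + 1)
    jx = np.arange(0, int(np.floor((w - 1) / pitch_px)) + 1)
    corners = np.stack(np.meshgrid(iy * pitch_px, jx * pitch_px, indexing="ij"),
                       axis=-1).astype(np.float64)
    if warp is not None:
        img = warp_image(img, warp)
        corners = warp_points(corners, warp, (h, w))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0.0, MAX_U16), corners


# ---------------------------------------------------------------------------
# on-disk fixture trees

def full_scale_brain_metadata(brain_id: str = "B0001", n_sections: int = 280,
                               ) -> BrainVolumeMetadata:
    """Metadata for a full-scale acquisition: 11 x 14 grid of 832 x 832 tiles,
    four channels, nominal 100 px overlap, 1.25 / 50 um spacing."""
    return BrainVolumeMetadata(
        brain_id=brain_id, n_sections=n_sections,
        tiles_per_row=14, tiles_per_col=11,
        tile_height_px=832, tile_width_px=832,
        n_channels=4, channel_names=("red", "green", "blue", "farred"),
        nominal_overlap_px=100, in_plane_spacing_um=1.25,
        section_spacing_um=50.0)


def write_fixture_tree(root_path: str | Path,
                       brain_meta: BrainVolumeMetadata,
                       step_y_px: int | None = None,
                       step_x_px: int | None = None,
                       margin_px: int = 4,
                       cell_density: float = 40.0,
                       noise_sd: float = 20.0,
                       gain: np.ndarray | None = None,
                       warp: SyntheticWarp | None = None,
                       seed: int = 0,
                       metadata_only: bool = False,
                       ) -> dict:
    """Write a complete synthetic acquisition tree under ``root_path``.

    Each section is an independent phantom sliced into the tile grid
    (optionally vignetted and warped) and written as 16-bit TIFFs with brain
    and section metadata files, exactly as :mod:`braintile.metadata_io` reads
    back.  ``metadata_only=True`` writes the folder structure and metadata
    but no pixel payloads (every tile will be flagged missing) so full-brain
    enumeration counts run in seconds.

    Returns ground truth: phantom sections, tile positions, steps, margin.
    """
    import tifffile

    if step_y_px is None:
        step_y_px = brain_meta.tile_height_px - brain_meta.nominal_overlap_px
    if step_x_px is None:
        step_x_px = brain_meta.tile_width_px - brain_meta.nominal_overlap_px
    rows, cols = brain_meta.tiles_per_col, brain_meta.tiles_per_row
    th, tw = brain_meta.tile_height_px, brain_meta.tile_width_px
    sec_h = (rows - 1) * step_y_px + th
    sec_w = (cols - 1) * step_x_px + tw
    canvas_h = margin_px + sec_h
    canvas_w = margin_px + sec_w

    brain_dir = Path(root_path) / brain_meta.brain_id
    brain_dir.mkdir(parents=True, exist_ok=True)
    (brain_dir / BRAIN_METADATA_FILENAME).write_text(
        serialize_brain_metadata(brain_meta))

    truth: dict = {"sections": {}, "positions": None,
                   "step_y_px": step_y_px, "step_x_px": step_x_px,
                   "margin_px": margin_px,
                   "canvas_shape": (canvas_h, canvas_w)}
    for s in range(brain_meta.n_sections):
        sec_dir = brain_dir / section_dirname(s)
        sec_dir.mkdir(exist_ok=True)
        (sec_dir / SECTION_METADATA_FILENAME).write_text(
            serialize_section_metadata(SectionMetadata(
                section_index=s, canvas_height_px=canvas_h,
                canvas_width_px=canvas_w, tiles_per_row=cols,
                tiles_per_col=rows, n_channels=brain_meta.n_channels,
                margin_px=margin_px)))
        if metadata_only:
            continue
        spec = PhantomSpec(height_px=sec_h, width_px=sec_w,
                           cell_density=cell_density, noise_sd=noise_sd,
                           seed=seed + s)
        section = generate_phantom_section(spec)
        truth["sections"][s] = section
        for ch_i, ch in enumerate(brain_meta.channel_names):
            # channels share geometry; give each a distinct brightness scale
            scale = 1.0 - 0.1 * ch_i
            tiles, positions = slice_into_tiles(
                section * scale, rows, cols, step_y_px, step_x_px, th, tw,
                gain=gain, warp=warp)
            truth["positions"] = positions
            for idx, tile in enumerate(tiles):
                r, c = divmod(idx, cols)
                out = np.clip(np.round(tile), 0, MAX_U16).astype(np.uint16)
                tifffile.imwrite(
                    sec_dir / tile_filename(brain_meta.brain_id, s, r, c, ch),
                    out)
    return truth
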