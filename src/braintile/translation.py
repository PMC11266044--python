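"""Inter-tile translation estimation by normalized cross-correlation.

Adjacent tiles overlap by a nominally fixed number of pixels.  For a
horizontal pair we take a wide strip (default 100 px) from the leading
tile's right edge and a narrow strip (default 50 px) from the trailing
tile's left edge, slide the narrow strip over the wide one, and score each
integer placement with normalized cross-correlation (NCC).  The argmax gives
the pair's true offset.  Because the stage is mechanically stable, offsets
are consistent across pairs, sections and scans, so the median over a small
sample of pairs yields global *translation parameters* that are estimated
once and reused.

All estimates are integer-pixel: tiles are placed on the canvas pixel by
pixel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

__all__ = ["StripConfig", "PairShift", "TranslationParams",
           "ncc_surface", "estimate_pair_shift",
           "estimate_translation_params", "central_pair_plan"]


@dataclass(frozen=True)
class StripConfig:
    """Strip widths and perpendicular search range for pair alignment."""

    wide_strip_px: int = 100
    narrow_strip_px: int = 50
    max_perpendicular_shift_px: int = 10
    confidence_floor: float = 0.3

    def __post_init__(self) -> None:
        if not (0 < self.narrow_strip_px < self.wide_strip_px):
            raise ValueError("require 0 < narrow_strip_px < wide_strip_px")
        if self.max_perpendicular_shift_px < 0:
            raise ValueError("max_perpendicular_shift_px must be >= 0")


@dataclass(frozen=True)
class PairShift:
    """Result of aligning one tile pair."""

    dx: int                     # trailing minus leading top-left offset, x
    dy: int                     # same, y
    peak_ncc: float
    confident: bool


@dataclass(frozen=True)
class TranslationParams:
    """Global integer inter-tile offsets used for canvas placement.

    ``step_x_px``: x-offset between horizontal neighbours; ``step_y_px``:
    y-offset between vertical neighbours; the two drift terms are the small
    perpendicular offsets accumulated per column / per row.
    """

    step_x_px: int
    step_y_px: int
    dy_at_horizontal_px: int = 0
    dx_at_vertical_px: int = 0
    n_pairs_used: int = 1
    mean_ncc: float = 1.0

    def __post_init__(self) -> None:
        if self.step_x_px <= 0 or self.step_y_px <= 0:
            raise ValueError("steps must be positive")
        if not (-1.0 <= self.mean_ncc <= 1.0):
            raise ValueError("mean_ncc must lie in [-1, 1]")

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TranslationParams":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------

def ncc_surface(template: np.ndarray, search: np.ndarray) -> np.ndarray:
    """NCC of ``template`` against every placement inside ``search``.

    Output shape is ``(Hs - Ht + 1, Ws - Wt + 1)``; each value is
    sum((a - mean a)(b - mean b)) / (N * sd_a * sd_b) over the overlap,
    in [-1, 1].  Placements where either the template or the window has zero
    variance are defined as 0 (no signal to align on).
    """
    t = np.asarray(template, dtype=np.float64)
    s = np.asarray(search, dtype=np.float64)
    th, tw = t.shape
    sh, sw = s.shape
    if th > sh or tw > sw:
        raise ValueError(
            f"template {t.shape} does not fit inside search {s.shape}")
    ny, nx = sh - th + 1, sw - tw + 1
    n = th * tw

    t0 = t - t.mean()
    t_ss = float((t0 * t0).sum())
    # stabilise window sums by removing the global mean of the search patch
    s0 = s - s.mean()
    out = np.empty((ny, nx))
    # window sums via integral images (O(1) per placement)
    ii = np.zeros((sh + 1, sw + 1))
    ii[1:, 1:] = s0.cumsum(0).cumsum(1)
    ii2 = np.zeros((sh + 1, sw + 1))
    ii2[1:, 1:] = (s0 * s0).cumsum(0).cumsum(1)

    def window_sum(mat, iy, ix):
        return (mat[iy + th, ix + tw] - mat[iy, ix + tw]
                - mat[iy + th, ix] + mat[iy, ix])

    iy_idx = np.arange(ny)[:, None]
    ix_idx = np.arange(nx)[None, :]
    wsum = window_sum(ii, iy_idx, ix_idx)
    wss = window_sum(ii2, iy_idx, ix_idx)
    wvar = np.maximum(wss - wsum * wsum / n, 0.0)

    if t_ss <= 1e-12 * n:
        return np.zeros((ny, nx))
    for iy in range(ny):
        win = s0[iy:iy + th]
        for ix in range(nx):
            out[iy, ix] = float((win[:, ix:ix + tw] * t0).sum())
    den = np.sqrt(t_ss * wvar)
    with np.errstate(invalid="ignore", divide="ignore"):
        ncc = np.where(den > 1e-9 * n, out / den, 0.0)
    return np.clip(ncc, -1.0, 1.0)


def _argmax_with_tiebreak(surface: np.ndarray,
                          preferred: tuple[int, int]) -> tuple[int, int]:
    """Argmax; among near-equal maxima pick the one closest to ``preferred``."""
    peak = surface.max()
    ys, xs = np.nonzero(surface >= peak - 1e-9)
    d2 = (ys - preferred[0]) ** 2 + (xs - preferred[1]) ** 2
    order = np.lexsort((xs, ys, d2))
    k = order[0]
    return int(ys[k]), int(xs[k])


def estimate_pair_shift(leading: np.ndarray, trailing: np.ndarray,
                        direction: str, cfg: StripConfig = StripConfig(),
                        nominal_overlap_px: int | None = None) -> PairShift:
    """Align one neighbouring tile pair and return its integer offset.

    ``direction='horizontal'``: trailing is the right neighbour; the result's
    ``dx`` is its x-offset relative to the leading tile (the step) and ``dy``
    the perpendicular drift.  ``'vertical'`` is the transpose case.  Ties in
    the NCC surface break toward the nominal overlap; a peak below the
    confidence floor flags the pair as unusable.
    """
    a = np.asarray(leading, dtype=np.float64)
    b = np.asarray(trailing, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("tiles must share a shape")
    if direction == "vertical":
        res = estimate_pair_shift(a.T, b.T, "horizontal", cfg, nominal_overlap_px)
        return PairShift(dx=res.dy, dy=res.dx, peak_ncc=res.peak_ncc,
                         confident=res.confident)
    if direction != "horizontal":
        raise ValueError(f"direction must be horizontal|vertical, got {direction!r}")

    H, W = a.shape
    wide, narrow, mp = (cfg.wide_strip_px, cfg.narrow_strip_px,
                        cfg.max_perpendicular_shift_px)
    if wide > W:
        raise ValueError("wide strip exceeds tile width")
    search = a[:, W - wide:]
    template = b[mp:H - mp if mp else H, :narrow]
    surface = ncc_surface(template, search)

    nominal = nominal_overlap_px if nominal_overlap_px is not None else wide
    pref_ix = int(np.clip(wide - nominal, 0, surface.shape[1] - 1))
    iy, ix = _argmax_with_tiebreak(surface, (mp, pref_ix))
    peak = float(surface[iy, ix])
    dx = W - wide + ix
    dy = iy - mp
    return PairShift(dx=dx, dy=dy, peak_ncc=peak,
                     confident=peak >= cfg.confidence_floor)


def central_pair_plan(rows: int, cols: int, max_pairs: int = 8,
                      ) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Deterministic sampling plan: tile pairs from the central third of the
    grid (texture-rich tissue).  Returns (horizontal, vertical) lists of the
    leading tile's (row, col)."""
    r0, r1 = rows // 3, max(rows // 3 + 1, rows - rows // 3)
    c0, c1 = cols // 3, max(cols // 3 + 1, cols - cols // 3)
    horizontal = [(r, c) for r in range(r0, r1) for c in range(c0, min(c1, cols - 1))]
    vertical = [(r, c) for r in range(r0, min(r1, rows - 1)) for c in range(c0, c1)]
    return horizontal[:max_pairs], vertical[:max_pairs]


def estimate_translation_params(
        get_tile: Callable[[int, int], np.ndarray],
        horizontal_pairs: Sequence[tuple[int, int]],
        vertical_pairs: Sequence[tuple[int, int]],
        cfg: StripConfig = StripConfig(),
        nominal_overlap_px: int | None = None) -> TranslationParams:
    """Aggregate pair estimates into global translation parameters.

    ``get_tile(row, col)`` returns the tile image; each listed pair is the
    leading tile of a horizontal (right neighbour) or vertical (bottom
    neighbour) pair.  Per direction the estimate is the median over confident
    pairs (robust to up to half the pairs being corrupted); a direction with
    no confident pair raises, advising a different section.
    """
    h_shifts, v_shifts, peaks = [], [], []
    for r, c in horizontal_pairs:
        res = estimate_pair_shift(get_tile(r, c), get_tile(r, c + 1),
                                  "horizontal", cfg, nominal_overlap_px)
        if res.confident:
            h_shifts.append((res.dx, res.dy))
            peaks.append(res.peak_ncc)
    for r, c in vertical_pairs:
        res = estimate_pair_shift(get_tile(r, c), get_tile(r + 1, c),
                                  "vertical", cfg, nominal_overlap_px)
        if res.confident:
            v_shifts.append((res.dy, res.dx))
            peaks.append(res.peak_ncc)
    if not h_shifts:
        raise RuntimeError("no confident horizontal pair; try a section with "
                           "more tissue texture")
    if not v_shifts:
        raise RuntimeError("no confident vertical pair; try a section with "
                           "more tissue texture")
    h_arr = np.asarray(h_shifts)
    v_arr = np.asarray(v_shifts)
    return TranslationParams(
        step_x_px=int(round(float(np.median(h_arr[:, 0])))),
        step_y_px=int(round(float(np.median(v_arr[:, 0])))),
        dy_at_horizontal_px=int(round(float(np.median(h_arr[:, 1])))),
        dx_at_vertical_px=int(round(float(np.median(v_arr[:, 1])))),
        n_pairs_used=len(h_shifts) + len(v_shifts),
        mean_ncc=float(np.mean(peaks)))
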