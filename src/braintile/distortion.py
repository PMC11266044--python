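"""Lens-distortion calibration and correction.

A mesh-grid target of known pitch is imaged once per instrument.  Calibration
proceeds in four steps:

1. detect the grid-cell corner lattice in the (distorted) target image,
   discarding partial cells at the image border;
2. build an ideal template lattice with exactly equal spacing and the same
   node count;
3. fit a global projective transform (homography) mapping detected corners
   onto the template;
4. model what the homography cannot explain — the locally varying residual —
   as a smooth bicubic-spline displacement field interpolating the per-node
   residuals exactly.

The composite forward map is baked into a dense per-pixel inverse lookup
table (LUT) over the tile shape, serialized so one calibration is reused for
every tile of every section and scan on the same instrument.  Correction is
plain inverse-mapped bilinear resampling through the LUT.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.interpolate import RectBivariateSpline
from skimage import measure
from skimage.filters import threshold_otsu

__all__ = [
    "CornerLattice",
    "Homography",
    "ResidualField",
    "DeformationModel",
    "CalibrationError",
    "detect_grid_corners",
    "build_template_lattice",
    "fit_homography",
    "fit_residual_spline",
    "build_correction_lut",
    "apply_correction",
    "calibrate_from_grid",
]


class CalibrationError(RuntimeError):
    pass


@dataclass
class CornerLattice:
    """Row/col-ordered grid of (y, x) corner coordinates."""

    points: np.ndarray          # (n_rows, n_cols, 2) float
    source: str                 # "detected" | "template"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 3 or self.points.shape[2] != 2:
            raise ValueError("points must have shape (n_rows, n_cols, 2)")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("lattice coordinates must be finite")

    @property
    def n_rows(self) -> int:
        return self.points.shape[0]

    @property
    def n_cols(self) -> int:
        return self.points.shape[1]

    def flat(self) -> np.ndarray:
        return self.points.reshape(-1, 2)


@dataclass(frozen=True)
class Homography:
    """3x3 projective transform on (y, x) points, normalized so H[2,2] = 1."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (3, 3):
            raise ValueError("homography must be 3x3")
        if abs(np.linalg.det(m)) <= 1e-12:
            raise ValueError("homography is singular")
        object.__setattr__(self, "matrix", m / m[2, 2])

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (..., 2) (y, x) points through the homography."""
        pts = np.asarray(points, dtype=np.float64)
        flat = pts.reshape(-1, 2)
        homog = np.column_stack([flat, np.ones(len(flat))])
        out = homog @ self.matrix.T
        return (out[:, :2] / out[:, 2:3]).reshape(pts.shape)

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.matrix))


# ---------------------------------------------------------------------------
# corner detection

def detect_grid_corners(grid: np.ndarray, expected_pitch_px: float,
                        ) -> CornerLattice:
    """Detect the cell-corner lattice of a mesh-grid target image.

    Bright holes are segmented by Otsu threshold and light morphological
    opening; connected components touching the image border (partial cells)
    or far from the expected cell area are discarded.  Complete cells are
    indexed by rounding their intensity-weighted centroids to the expected
    pitch, and each interior lattice node — a corner shared by four complete
    cells — is estimated as the mean of those four centroids (exact under
    affine distortion, sub-pixel for smooth warps).
    """
    img = np.asarray(grid, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("grid image must be 2D")
    thr = threshold_otsu(img)
    holes = img > thr  # holes are the bright phase of a mesh-grid target
    holes = ndimage.binary_opening(holes, structure=np.ones((3, 3)))
    labels = measure.label(holes, connectivity=1)
    h, w = img.shape
    border = set(np.unique(np.concatenate([
        labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])))
    min_area = 0.25 * (expected_pitch_px * 0.5) ** 2
    centroids = []
    weights = np.where(holes, img - thr, 0.0)
    for region in measure.regionprops(labels, intensity_image=weights):
        if region.label in border:
            continue
        if region.area < min_area:
            continue
        centroids.append(region.centroid_weighted)
    if len(centroids) < 4:
        raise CalibrationError(
            f"only {len(centroids)} complete grid cells found; need >= 4")
    cent = np.asarray(centroids, dtype=np.float64)

    # index cells on the integer lattice implied by the expected pitch
    origin = cent.min(axis=0)
    idx = np.round((cent - origin) / expected_pitch_px).astype(int)
    n_i, n_j = idx[:, 0].max() + 1, idx[:, 1].max() + 1
    cells = np.full((n_i, n_j, 2), np.nan)
    for (ci, cj), c in zip(idx, cent):
        cells[ci, cj] = c
    if n_i < 2 or n_j < 2:
        raise CalibrationError("fewer than 2x2 complete cells detected")

    # interior nodes: mean of the four adjacent cell centroids
    quad = (cells[:-1, :-1] + cells[:-1, 1:] + cells[1:, :-1] + cells[1:, 1:]) / 4.0
    valid = ~np.isnan(quad).any(axis=2)
    if not valid.all():
        # keep the largest contiguous fully valid sub-rectangle
        i0, i1, j0, j1 = _largest_true_rectangle(valid)
        quad = quad[i0:i1, j0:j1]
    if quad.shape[0] < 2 or quad.shape[1] < 2:
        raise CalibrationError("corner lattice smaller than 2x2")
    return CornerLattice(points=quad, source="detected")


def _largest_true_rectangle(valid: np.ndarray) -> tuple[int, int, int, int]:
    """Largest all-True axis-aligned rectangle (i0, i1, j0, j1), half-open.

    Brute force over row ranges with column prefix sums; lattices are tens of
    nodes, so O(n_rows^2 * n_cols) is instant.  Ties break toward the
    top-left for determinism.
    """
    n_i, n_j = valid.shape
    col_pref = np.zeros((n_i + 1, n_j), dtype=int)
    col_pref[1:] = np.cumsum(valid, axis=0)
    best = (0, 0, 0, 0)
    best_area = 0
    for i0 in range(n_i):
        for i1 in range(i0 + 1, n_i + 1):
            ok = (col_pref[i1] - col_pref[i0]) == (i1 - i0)
            # longest run of True columns
            j = 0
            while j < n_j:
                if not ok[j]:
                    j += 1
                    continue
                j_end = j
                while j_end < n_j and ok[j_end]:
                    j_end += 1
                area = (i1 - i0) * (j_end - j)
                if area > best_area:
                    best_area = area
                    best = (i0, i1, j, j_end)
                j = j_end
    if best_area == 0:
        raise CalibrationError("could not assemble a complete corner lattice")
    return best


def build_template_lattice(n_rows: int, n_cols: int, pitch_px: float,
                           origin: tuple[float, float] = (0.0, 0.0),
                           ) -> CornerLattice:
    """Ideal lattice: exactly equally spaced nodes, ``pitch_px`` apart."""
    if n_rows < 2 or n_cols < 2:
        raise ValueError("template lattice must be at least 2x2")
    ys = origin[0] + pitch_px * np.arange(n_rows)
    xs = origin[1] + pitch_px * np.arange(n_cols)
    points = np.stack(np.meshgrid(ys, xs, indexing="ij"), axis=-1)
    return CornerLattice(points=points, source="template")


# ---------------------------------------------------------------------------
# homography

def fit_homography(src: CornerLattice, dst: CornerLattice) -> Homography:
    """Least-squares projective fit mapping ``src`` points onto ``dst``.

    Normalized DLT over all correspondences; for an exact projective
    relation the residual is at numerical precision.
    """
    if src.points.shape != dst.points.shape:
        raise ValueError("lattices must have the same shape")
    s = src.flat()
    d = dst.flat()
    if len(s) < 4:
        raise ValueError("need at least 4 correspondences")

    def normalizer(pts):
        mean = pts.mean(axis=0)
        scale = np.sqrt(2.0) / max(np.sqrt(((pts - mean) ** 2).sum(axis=1)).mean(), 1e-12)
        T = np.array([[scale, 0, -scale * mean[0]],
                      [0, scale, -scale * mean[1]],
                      [0, 0, 1.0]])
        return T

    Ts, Td = normalizer(s), normalizer(d)
    sn = (np.column_stack([s, np.ones(len(s))]) @ Ts.T)[:, :2]
    dn = (np.column_stack([d, np.ones(len(d))]) @ Td.T)[:, :2]

    A = np.zeros((2 * len(sn), 9))
    for k, ((y, x), (v, u)) in enumerate(zip(sn, dn)):
        A[2 * k] = [y, x, 1, 0, 0, 0, -v * y, -v * x, -v]
        A[2 * k + 1] = [0, 0, 0, y, x, 1, -u * y, -u * x, -u]
    _, sv, vt = np.linalg.svd(A)
    if sv[-2] < 1e-10 * sv[0]:
        raise ValueError("degenerate correspondences (collinear points)")
    Hn = vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ Hn @ Ts
    return Homography(H)


# ---------------------------------------------------------------------------
# residual spline

@dataclass
class ResidualField:
    """Smooth (dy, dx) displacement field over the template lattice.

    Bicubic-spline interpolation of the per-node displacements, evaluated
    with coordinates clamped to the lattice bounding box (clamped
    extrapolation beyond the hull).
    """

    node_ys: np.ndarray
    node_xs: np.ndarray
    node_dy: np.ndarray         # (n_rows, n_cols)
    node_dx: np.ndarray
    _sy: RectBivariateSpline = field(init=False, repr=False)
    _sx: RectBivariateSpline = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ky = min(3, len(self.node_ys) - 1)
        kx = min(3, len(self.node_xs) - 1)
        self._sy = RectBivariateSpline(self.node_ys, self.node_xs,
                                       self.node_dy, kx=kx, ky=ky, s=0)
        self._sx = RectBivariateSpline(self.node_ys, self.node_xs,
                                       self.node_dx, kx=kx, ky=ky, s=0)

    def evaluate(self, ys: np.ndarray, xs: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
        yc = np.clip(ys, self.node_ys[0], self.node_ys[-1])
        xc = np.clip(xs, self.node_xs[0], self.node_xs[-1])
        return self._sy.ev(yc, xc), self._sx.ev(yc, xc)


def fit_residual_spline(projected: CornerLattice, template: CornerLattice,
                        ) -> ResidualField:
    """Interpolate the per-node displacements ``template - projected``.

    The field lives on the template's (regular) lattice and reproduces the
    node displacements exactly; between nodes it is the natural bicubic
    spline through them.
    """
    if projected.points.shape != template.points.shape:
        raise ValueError("lattice shapes differ")
    d = template.points - projected.points
    node_ys = template.points[:, 0, 0]
    node_xs = template.points[0, :, 1]
    return ResidualField(node_ys=node_ys, node_xs=node_xs,
                         node_dy=d[..., 0], node_dx=d[..., 1])


# ---------------------------------------------------------------------------
# dense LUT model

@dataclass
class DeformationModel:
    """Reusable lens-distortion correction.

    ``dense_lut`` holds, for every output (corrected) pixel, the source
    coordinate in the distorted image: shape (2, H, W) float32 (y then x).
    """

    homography: Homography
    residual: ResidualField | None
    dense_lut: np.ndarray
    tile_shape: tuple[int, int]
    metadata: dict

    def forward_points(self, points: np.ndarray) -> np.ndarray:
        """Forward map distorted -> corrected for (..., 2) (y, x) points."""
        u = self.homography.apply(points)
        if self.residual is not None:
            dy, dx = self.residual.evaluate(u[..., 0].ravel(), u[..., 1].ravel())
            u = u.copy()
            u[..., 0] += dy.reshape(u[..., 0].shape)
            u[..., 1] += dx.reshape(u[..., 1].shape)
        return u

    def save(self, path: str | Path) -> None:
        """Compressed array file (.npz) with a JSON header; bit-exact reuse."""
        payload = {
            "lut": self.dense_lut.astype(np.float32),
            "homography": self.homography.matrix,
            "header_json": np.frombuffer(
                json.dumps(self.metadata).encode(), dtype=np.uint8),
        }
        if self.residual is not None:
            payload.update(node_ys=self.residual.node_ys,
                           node_xs=self.residual.node_xs,
                           node_dy=self.residual.node_dy,
                           node_dx=self.residual.node_dx)
        np.savez_compressed(path, **payload)

    @classmethod
    def load(cls, path: str | Path) -> "DeformationModel":
        with np.load(path) as z:
            lut = z["lut"]
            hom = Homography(z["homography"])
            meta = json.loads(bytes(z["header_json"]).decode())
            residual = None
            if "node_ys" in z:
                residual = ResidualField(node_ys=z["node_ys"], node_xs=z["node_xs"],
                                         node_dy=z["node_dy"], node_dx=z["node_dx"])
        return cls(homography=hom, residual=residual, dense_lut=lut,
                   tile_shape=tuple(lut.shape[1:]), metadata=meta)

    @classmethod
    def identity(cls, tile_shape: tuple[int, int]) -> "DeformationModel":
        lut = np.mgrid[0:tile_shape[0], 0:tile_shape[1]].astype(np.float32)
        return cls(homography=Homography(np.eye(3)), residual=None,
                   dense_lut=lut, tile_shape=tile_shape,
                   metadata={"kind": "identity"})


def build_correction_lut(h: Homography, residual: ResidualField | None,
                         tile_shape: tuple[int, int],
                         n_iter: int = 10) -> DeformationModel:
    """Bake the composite forward map F = residual o homography into a dense
    inverse lookup table over ``tile_shape``.

    For each output pixel q we solve u + D(u) = q by fixed-point iteration
    (D is the clamped residual field), then s = H^{-1}(u) is the source pixel.
    Raises :class:`CalibrationError` if the inversion does not converge
    (non-invertible composite inside the tile).
    """
    H, W = tile_shape
    qy, qx = np.mgrid[0:H, 0:W].astype(np.float64)
    uy, ux = qy.copy(), qx.copy()
    if residual is not None:
        for _ in range(n_iter):
            dy, dx = residual.evaluate(uy.ravel(), ux.ravel())
            uy = qy - dy.reshape(H, W)
            ux = qx - dx.reshape(H, W)
        dy, dx = residual.evaluate(uy.ravel(), ux.ravel())
        res = np.hypot(uy + dy.reshape(H, W) - qy, ux + dx.reshape(H, W) - qx)
        if res.max() > 0.1:
            j = np.unravel_index(np.argmax(res), res.shape)
            raise CalibrationError(
                f"residual field not invertible near pixel {j} "
                f"(fixed-point residual {res.max():.3f} px)")
    hinv = h.inverse()
    src = hinv.apply(np.stack([uy, ux], axis=-1))
    lut = np.stack([src[..., 0], src[..., 1]]).astype(np.float32)
    if not np.all(np.isfinite(lut)):
        raise CalibrationError("non-finite source coordinates in LUT")
    meta = {"tile_shape": [H, W]}
    return DeformationModel(homography=h, residual=residual, dense_lut=lut,
                            tile_shape=(H, W), metadata=meta)


def apply_correction(tile: np.ndarray, model: DeformationModel) -> np.ndarray:
    """Resample a tile through the model's LUT (bilinear, edge-replicated).

    Output shape and dtype equal the input's; an identity model is a no-op.
    """
    img = np.asarray(tile)
    if img.shape != model.tile_shape:
        raise ValueError(
            f"tile shape {img.shape} != model tile shape {model.tile_shape}")
    return ndimage.map_coordinates(img, model.dense_lut, order=1, mode="nearest")


# ---------------------------------------------------------------------------
# end-to-end calibration

def calibrate_from_grid(grid: np.ndarray, expected_pitch_px: float,
                        tile_shape: tuple[int, int] | None = None,
                        template: CornerLattice | None = None,
                        max_corner_rms_px: float = 0.5,
                        metadata: dict | None = None) -> DeformationModel:
    """Calibrate a deformation model from one grid-target image.

    Detects corners, builds the matching equally spaced template (centred on
    the detected cloud unless an explicit ``template`` is given), fits the
    homography and residual spline, and bakes the dense LUT.  Fails if the
    calibrated model leaves detected corners more than ``max_corner_rms_px``
    RMS away from the template.
    """
    grid = np.asarray(grid, dtype=np.float64)
    if tile_shape is None:
        tile_shape = grid.shape
    detected = detect_grid_corners(grid, expected_pitch_px)
    if template is None:
        center = detected.flat().mean(axis=0)
        origin = (center[0] - expected_pitch_px * (detected.n_rows - 1) / 2.0,
                  center[1] - expected_pitch_px * (detected.n_cols - 1) / 2.0)
        template = build_template_lattice(detected.n_rows, detected.n_cols,
                                          expected_pitch_px, origin)
    elif (template.n_rows, template.n_cols) != (detected.n_rows, detected.n_cols):
        raise CalibrationError(
            f"template {template.n_rows}x{template.n_cols} does not match "
            f"detected lattice {detected.n_rows}x{detected.n_cols}")
    h = fit_homography(detected, template)
    projected = CornerLattice(points=h.apply(detected.points), source="detected")
    residual = fit_residual_spline(projected, template)
    model = build_correction_lut(h, residual, tile_shape)
    corrected = model.forward_points(detected.points)
    rms = float(np.sqrt(((corrected - template.points) ** 2).sum(axis=-1).mean()))
    if rms > max_corner_rms_px:
        raise CalibrationError(
            f"calibration residual RMS {rms:.3f} px exceeds "
            f"{max_corner_rms_px} px")
    model.metadata.update(metadata or {})
    model.metadata.update(grid_pitch_px=expected_pitch_px, corner_rms_px=rms,
                          lattice_shape=[detected.n_rows, detected.n_cols])
    return model
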