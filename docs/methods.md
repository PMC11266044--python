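# Methods

## Data model

An acquisition is a folder per brain holding a plain-text brain-volume
metadata file and one folder per section, each with a section metadata file
and one single-plane grayscale TIFF per (row, col, channel). Metadata is a
`key: value` dialect (UTF-8, `#` comments) chosen for diffability; the tile
file-name scheme `<brain>_S%04d_R%02d_C%02d_<channel>.tif` makes missing-tile
detection deterministic: enumeration always yields the full Cartesian
product `n_sections × rows × cols × channels` of records, and a record whose
file is absent is flagged missing and loads as an all-zero placeholder of
the standard tile shape, so no downstream stage ever sees a hole. Tile
indices are 0-based (row, col), y-down, raster order; a serpentine stage
scan would change only the index-to-file mapping in `metadata_io`.

## Flat-field (brightness) normalization

Vignetting is modelled as a fixed per-channel multiplicative gain. The
profile is the per-pixel arithmetic mean over all non-missing tiles of a
channel — by default across the whole brain, because tiles of the same grid
position in different sections decorrelate the tissue and leave only the
optical pattern; a `per_section` scope exists for drifting illumination.
Correction divides each pixel by `max(profile, ε)` with
`ε = max(1e-6, 1e-3 · mean(profile))`, a floor that only guards dead pixels.
Output is deliberately **not** clamped to [0, 1]: labelled cells brighter
than the average tissue must stay brighter. Canvases are converted back to
the storage dtype at write time by a configurable rescale (default: multiply
by the profile mean), keeping the original intensity regime.

How many tiles the profile averages matters: with `N` tiles the tissue
texture leaks into the profile at amplitude ∝ 1/N. The real acquisition
averages tens of thousands of tiles; the test fixtures use ≥ 80 tiles per
channel, enough to push the leakage below the 1–2% error budgets the tests
assert.

## Lens-distortion calibration

The instrument images a mesh grid of known pitch once. Corner detection:
Otsu threshold on the bright holes, 3×3 binary opening, connected
components; components touching the image border (partial cells) or smaller
than a quarter of the expected hole area are discarded; each surviving cell
contributes an intensity-weighted centroid; cells are indexed by rounding
centroids to the expected pitch; and each interior lattice node is the mean
of its four adjacent cell centroids. That mean is exact under affine
distortion and has `O(amplitude · pitch² / smoothness²)` error for smooth
warps — measured well under 0.1 px on the synthetic targets. If missing
cells fragment the lattice, the largest contiguous complete sub-rectangle is
kept (never a stitched-together set of non-adjacent rows, which would
scramble the correspondence).

The equally spaced template lattice has the same node count, the nominal
pitch, and is centred on the detected cloud (an explicit template can be
supplied when the true lattice origin is known). A normalized-DLT
least-squares homography maps detected onto template corners; the residual
per-node displacements `template − H(detected)` are interpolated by one C²
bicubic spline per component over the template's regular lattice (a bicubic
spline through a Bezier control net is the same surface up to basis change,
so a single spline stands in for per-cell patches). Evaluation clamps
coordinates to the lattice bounding box — constant extrapolation beyond the
hull, which cannot blow up.

The composite forward map `F = (id + S) ∘ H` is inverted per output pixel by
fixed-point iteration (`u ← q − S(u)`, 10 iterations, convergence checked
against a 0.1 px tolerance) and baked into a dense float32 (y, x) source-
coordinate LUT over the tile shape, stored as a compressed `.npz` with a
JSON header. Correction is inverse-mapped bilinear resampling with
edge-replicated out-of-bounds sources (no ringing, bounded values);
the identity LUT reproduces the input bit-for-bit. One model is shared by
all channels by default. Calibration fails loudly if the corrected corners
sit more than 0.5 px RMS from the template.

## Translation estimation

Strips: wide (default 100 px) from the leading tile's trailing edge, narrow
(default 50 px) from the trailing tile's leading edge, trimmed by ±10 px for
the perpendicular search. NCC is computed exactly (window sums via integral
images on the mean-subtracted search patch; the cross term as a direct dot
product per placement), values clipped to [−1, 1]; zero-variance placements
are defined as 0 and a pair whose peak falls below 0.3 is excluded as
low-confidence. Estimates are integer-pixel — placement is pixel-by-pixel —
with ties broken toward the nominal overlap for determinism. Per direction
the global step is the median over confident pairs (robust to ⌊(n−1)/2⌋
corrupted pairs), sampled by default from the central third of a middle
section where tissue texture is richest. When the pipeline estimates
parameters itself it scales the strip widths with the metadata's nominal
overlap so the search range brackets it; with no confident pair anywhere it
falls back to the nominal overlap and records that in the parameters'
`mean_ncc = 0`.

## Stitching

Tile (r, c) lands at `y0 = margin + r·step_y + c·dy_drift`,
`x0 = margin + c·step_x + r·dx_drift`. The canvas consistency check uses
`margin + (n−1)·step + tile` per axis (margin applied at the top-left): with
the full-scale geometry — 11 × 14 tiles of 832 px, steps (788, 800), margin
4 — this reproduces an 8,716 × 11,236 px section exactly. A canvas that
disagrees with the arithmetic warns and is trusted; a placement that
overflows it is an error that prints the arithmetic.

Overlaps are never trimmed. Feather blending weights each tile by the
product of two per-axis linear ramps (1/depth at edge pixels up to 1 at the
overlap depth, which defaults to the smallest observed overlap between
placements); output pixels are the weight-normalized mean. Separable
product weights make the perpendicular ramp cancel between edge-sharing
tiles, so the blend ramps cleanly across every seam even near canvas
borders. Weights are strictly positive, hence single-coverage pixels are
reproduced exactly and blended values never leave the covering tiles' range.
Plain averaging (`mean`) is available; feathering reduces to it at the
overlap midline. All-zero placeholder tiles participate with their zeros —
a visible dark rectangle is preferred over silently inventing data.

## Volume assembly and export

Sections stack in index order into a (z, y, x) array; gaps are an error
unless explicitly zero-filled. Spacing defaults to (50, 1.25, 1.25) µm.
NIfTI-1 stores the transposed (x, y, z) array with spacing in mm in the
header zooms and a scaled-identity affine — the anatomical orientation of
the mount is not calibrated, and the affine says so by carrying no rotation.
Downsampling is block-mean by the integer factors nearest to
target/source spacing (trailing partial blocks dropped), with integer
volumes rounded back to their dtype; default targets 10 µm and 50 µm
in-plane, clamped per axis to never upsample z. The OME-Zarr writer emits
an NGFF 0.4 multiscale group (zarr v2 on-disk format): level 0 is the
volume after an exposure rescale mapping the (0.5, 99.5) intensity
percentiles onto the full dtype range, each further level a 2× y/x block
mean; chunks default to (1, 512, 512) for section-aligned reads; per-level
physical scales are recorded in the NGFF coordinate transformations. The
viewer URL embeds a sorted-key JSON state pointing a zarr image layer at the
store, so it is byte-deterministic.

## Pipelines and determinism

Workflow 1 freezes the shared inputs (profiles, translation parameters,
deformation model) to disk, then processes sections independently — in a
process pool when `workers > 1`. Because every (section, channel) canvas
depends only on its own tiles and those frozen inputs, outputs are
bit-identical for any worker count; the test suite checks checksums and raw
bytes for 1 vs 3 workers. Per-section failures are recorded in the JSON run
manifest (config snapshot, per-section tile/missing/clipped counts, stage
timings, output checksums), which is written even when the run aborts.

## What the synthetic fixtures do and do not show

Phantoms are Gaussian-profile disks (σ = radius/2) with uniform per-cell
amplitude factors on a constant background plus Gaussian noise — enough
texture for NCC and reconstruction oracles, deterministic in the seed.
Synthetic warps are de-meaned smoothed Gaussian fields rescaled to a chosen
maximum displacement; grid targets are rendered with 4× supersampled area
coverage so bar/hole pixel mass matches the continuous geometry and hole
centroids sit exactly on the lattice. Fixtures default to the full-scale
geometry (832 px tiles, 11 × 14 grid, 4 channels, 100 px nominal overlap,
16-bit TIFF) but tests run scaled-down layouts (128–400 px tiles, 2×2 to
3×3 grids, 2–20 sections) to keep the suite in seconds. Not modelled:
optical sectioning physics, fluorophore spectra, stage serpentine mechanics,
depth-dependent scattering, or chromatic per-channel distortion — so
passing tests demonstrate the correctness of the numerics on their stated
models, not robustness to every instrument pathology.

## Known limitations

- No subpixel or per-tile local registration, and no global mosaic
  optimization: the stage is assumed uniform, as the single global step
  model implies. A parabolic peak refinement exists but is off by default.
- One deformation model for all channels; chromatic differences are ignored.
- The grid target must be roughly axis-aligned (< ~10° skew); corner
  ordering is undefined beyond that and calibration errors out via the
  lattice-indexing checks.
- NIfTI orientation metadata is a scaled identity; registration to an atlas
  space is out of scope.
- The metadata-dialect nominal overlap is advisory only; the estimator
  always re-measures the true steps.
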