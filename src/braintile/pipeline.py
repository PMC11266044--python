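"""End-to-end orchestration of the two workflows.

Workflow 1 (tile adjustment and stitching): read metadata, enumerate tiles,
compute flat-field profiles, load + normalize + distortion-correct every
tile, group by section, and stitch one canvas per (section, channel).

Workflow 2 (2D -> 3D and visualization): stack the stitched sections into a
volume per channel, write NIfTI (full resolution plus downsampled), a
multiscale OME-Zarr store, and a viewer URL.

Sections are processed independently (optionally in a process pool); outputs
are bit-identical regardless of the worker count, because each (section,
channel) canvas depends only on its own tiles and the shared profiles /
model / parameters, which are frozen to disk before the pool starts.  A run
manifest (JSON) records the config snapshot, per-section status, stage
timings and output checksums, and is written even when sections fail.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from . import flatfield, metadata_io, stitching, translation, volume as vol_mod
from .distortion import DeformationModel, apply_correction
from .metadata_io import BrainVolumeMetadata, TileRecord

__all__ = ["PipelineConfig", "RunManifest", "compute_profiles",
           "run_stitch_pipeline", "run_volume_pipeline"]


@dataclass
class PipelineConfig:
    input_root: str
    output_root: str
    brain_id: str
    channels: list[str] | None = None       # None = all channels
    profile_scope: str = "brain"            # "brain" | "section"
    model_path: str | None = None           # deformation model (.npz); None = identity
    params_path: str | None = None          # translation params JSON; None = estimate
    blend: str = "feather"
    workers: int = 1
    seed: int = 0
    rescale: str | float = "profile_mean"   # back to storage dtype at write time
    fail_fast: bool = False
    # volume stage
    n_levels: int = 3
    downsample_targets_um: tuple[float, ...] = (10.0, 50.0)
    exposure_percentiles: tuple[float, float] = (0.5, 99.5)
    viewer_host: str = "https://neuroglancer-demo.appspot.com"

    def __post_init__(self) -> None:
        if self.workers < 1:
            raise ValueError("worker count must be >= 1")
        if self.profile_scope not in ("brain", "section"):
            raise ValueError("profile_scope must be 'brain' or 'section'")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        d["downsample_targets_um"] = list(self.downsample_targets_um)
        d["exposure_percentiles"] = list(self.exposure_percentiles)
        return d


@dataclass
class RunManifest:
    config: dict
    sections: dict = field(default_factory=dict)   # index -> status dict
    timings_s: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    errors: list = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         sort_keys=True, default=str))

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _tree_sha256(root: Path) -> str:
    """Order-independent checksum of a directory tree (e.g. a zarr store)."""
    h = hashlib.sha256()
    for p in sorted(root.rglob("*")):
        if p.is_file():
            h.update(p.relative_to(root).as_posix().encode())
            h.update(_sha256(p).encode())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# profiles, model, params preparation

def compute_profiles(records: list[TileRecord], meta: BrainVolumeMetadata,
                     channels: list[str]) -> dict[str, flatfield.Profile]:
    """One flat-field profile per channel from all non-missing tiles."""
    profiles = {}
    for ch in channels:
        tiles = (metadata_io.load_tile(r, meta) for r in records
                 if r.channel == ch and not r.missing)
        profiles[ch] = flatfield.compute_profile(tiles, channel=ch)
    return profiles


def _estimate_params(brain_dir: Path, meta: BrainVolumeMetadata,
                     records: list[TileRecord],
                     profile: flatfield.Profile) -> translation.TranslationParams:
    """Estimate translation parameters from the middle section's central
    pairs on normalized tiles of the first channel; fall back to the nominal
    overlap if no pair is confident."""
    mid = meta.n_sections // 2
    ch = meta.channel_names[0]
    by_pos = {(r.row, r.col): r for r in records
              if r.section_index == mid and r.channel == ch}

    def get_tile(row: int, col: int) -> np.ndarray:
        return flatfield.normalize_tile(
            metadata_io.load_tile(by_pos[(row, col)], meta), profile)

    hpairs, vpairs = translation.central_pair_plan(
        meta.tiles_per_col, meta.tiles_per_row)
    # strip widths scale with the nominal overlap so the NCC search range
    # brackets it (the 100/50 defaults assume a ~100 px overlap)
    if meta.nominal_overlap_px:
        cfg = translation.StripConfig(
            wide_strip_px=meta.nominal_overlap_px,
            narrow_strip_px=max(meta.nominal_overlap_px // 2, 4))
    else:
        cfg = translation.StripConfig()
    try:
        return translation.estimate_translation_params(
            get_tile, hpairs, vpairs, cfg,
            nominal_overlap_px=meta.nominal_overlap_px or None)
    except RuntimeError:
        if not meta.nominal_overlap_px:
            raise
        step = meta.tile_width_px - meta.nominal_overlap_px
        step_y = meta.tile_height_px - meta.nominal_overlap_px
        return translation.TranslationParams(step_x_px=step, step_y_px=step_y,
                                             n_pairs_used=1, mean_ncc=0.0)


# ---------------------------------------------------------------------------
# per-section worker (module-level so it pickles for the process pool)

def _process_section(input_root: str, output_dir: str, brain_id: str,
                     section_index: int, channels: list[str],
                     profile_dir: str, model_path: str | None,
                     params_path: str, blend: str,
                     rescale: str | float, profile_scope: str) -> dict:
    t0 = time.perf_counter()
    brain_dir = Path(input_root) / brain_id
    meta = metadata_io.read_brain_metadata(brain_dir)
    sec_meta = metadata_io.read_section_metadata(brain_dir, section_index)
    params = translation.TranslationParams.load(params_path)
    model = (DeformationModel.load(model_path) if model_path
             else DeformationModel.identity((meta.tile_height_px,
                                             meta.tile_width_px)))
    records = [r for r in metadata_io.enumerate_tiles(Path(input_root), meta)
               if r.section_index == section_index]
    placements = stitching.compute_tile_positions(
        sec_meta, params, (meta.tile_height_px, meta.tile_width_px))
    status = {"tiles_loaded": 0, "missing_tiles": 0, "clipped_pixels": 0,
              "outputs": []}
    for ch in channels:
        if profile_scope == "section":
            profile = flatfield.compute_profile(
                (metadata_io.load_tile(r, meta) for r in records
                 if r.channel == ch and not r.missing), channel=ch)
        else:
            profile = flatfield.load_profile(Path(profile_dir) / f"profile_{ch}.tif")
        by_pos = {(r.row, r.col): r for r in records if r.channel == ch}
        tiles = []
        for p in placements:
            rec = by_pos[(p.row, p.col)]
            tile = metadata_io.load_tile(rec, meta)
            status["tiles_loaded"] += 1
            status["missing_tiles"] += int(rec.missing)
            norm = flatfield.normalize_tile(tile, profile)
            tiles.append(apply_correction(norm, model))
        canvas = stitching.stitch_section(
            tiles, placements,
            (sec_meta.canvas_height_px, sec_meta.canvas_width_px), blend=blend)
        factor = profile.mean if rescale == "profile_mean" else float(rescale)
        out_path = Path(output_dir) / (
            f"{brain_id}_S{section_index:04d}_{ch}_stitched.tif")
        status["clipped_pixels"] += stitching.write_section(
            canvas, out_path, rescale=factor)
        status["outputs"].append(str(out_path))
    status["duration_s"] = round(time.perf_counter() - t0, 4)
    return status


# ---------------------------------------------------------------------------
# workflows

def run_stitch_pipeline(config: PipelineConfig) -> RunManifest:
    """Workflow 1: metadata -> load -> normalize -> correct -> stitch.

    Writes one TIFF per (section, channel) under ``<output_root>/sections``
    plus frozen profiles/params and a manifest.  Section outputs are
    independent of ``config.workers``.
    """
    manifest = RunManifest(config=config.snapshot())
    out_root = Path(config.output_root)
    sections_dir = out_root / "sections"
    profile_dir = out_root / "profiles"
    sections_dir.mkdir(parents=True, exist_ok=True)
    profile_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_root / "stitch_manifest.json"
    t_start = time.perf_counter()
    try:
        brain_dir = Path(config.input_root) / config.brain_id
        meta = metadata_io.read_brain_metadata(brain_dir)
        channels = config.channels or list(meta.channel_names)
        t0 = time.perf_counter()
        records = metadata_io.enumerate_tiles(Path(config.input_root), meta)
        manifest.timings_s["enumerate"] = round(time.perf_counter() - t0, 4)

        t0 = time.perf_counter()
        profiles = compute_profiles(records, meta, channels)
        for ch, prof in profiles.items():
            flatfield.save_profile(prof, profile_dir / f"profile_{ch}.tif")
        manifest.timings_s["profiles"] = round(time.perf_counter() - t0, 4)

        params_path = out_root / "translation_params.json"
        if config.params_path:
            params = translation.TranslationParams.load(config.params_path)
        else:
            t0 = time.perf_counter()
            params = _estimate_params(brain_dir, meta, records,
                                      profiles[channels[0]])
            manifest.timings_s["shift_estimation"] = round(
                time.perf_counter() - t0, 4)
        params.save(params_path)
        manifest.outputs["translation_params"] = str(params_path)

        args = [(config.input_root, str(sections_dir), config.brain_id, s,
                 channels, str(profile_dir), config.model_path,
                 str(params_path), config.blend, config.rescale,
                 config.profile_scope)
                for s in range(meta.n_sections)]
        t0 = time.perf_counter()
        if config.workers == 1:
            results = []
            for a in args:
                try:
                    results.append(_process_section(*a))
                except Exception as exc:  # noqa: BLE001 - recorded per section
                    manifest.errors.append(
                        {"section": a[3], "error": repr(exc)})
                    if config.fail_fast:
                        raise
                    results.append(None)
        else:
            with ProcessPoolExecutor(max_workers=config.workers) as pool:
                futures = [pool.submit(_process_section, *a) for a in args]
                results = []
                for a, fut in zip(args, futures):
                    try:
                        results.append(fut.result())
                    except Exception as exc:  # noqa: BLE001
                        manifest.errors.append(
                            {"section": a[3], "error": repr(exc)})
                        if config.fail_fast:
                            raise
                        results.append(None)
        manifest.timings_s["stitch"] = round(time.perf_counter() - t0, 4)
        for s, status in enumerate(results):
            if status is not None:
                manifest.sections[str(s)] = status
                for out in status["outputs"]:
                    manifest.checksums[Path(out).name] = _sha256(Path(out))
    finally:
        manifest.timings_s["total"] = round(time.perf_counter() - t_start, 4)
        manifest.write(manifest_path)
    return manifest


def run_volume_pipeline(config: PipelineConfig) -> RunManifest:
    """Workflow 2: stitched sections -> NIfTI (+ downsampled) -> OME-Zarr -> URL."""
    manifest = RunManifest(config=config.snapshot())
    out_root = Path(config.output_root)
    sections_dir = out_root / "sections"
    volumes_dir = out_root / "volumes"
    volumes_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_root / "volume_manifest.json"
    t_start = time.perf_counter()
    try:
        brain_dir = Path(config.input_root) / config.brain_id
        meta = metadata_io.read_brain_metadata(brain_dir)
        channels = config.channels or list(meta.channel_names)
        spacing = (meta.section_spacing_um, meta.in_plane_spacing_um,
                   meta.in_plane_spacing_um)
        for ch in channels:
            sections = {}
            missing = []
            for s in range(meta.n_sections):
                p = sections_dir / f"{config.brain_id}_S{s:04d}_{ch}_stitched.tif"
                if not p.exists():
                    missing.append(s)
                    continue
                sections[s] = tifffile.imread(p)
            if missing:
                raise FileNotFoundError(
                    f"channel {ch}: missing stitched sections {missing}")
            vol = vol_mod.stack_sections(sections, spacing_um=spacing,
                                         channel=ch, brain_id=config.brain_id)
            nii = volumes_dir / f"{config.brain_id}_{ch}.nii.gz"
            vol_mod.write_nifti(vol, nii)
            manifest.checksums[nii.name] = _sha256(nii)
            manifest.outputs.setdefault(ch, {})["nifti"] = str(nii)
            for target in config.downsample_targets_um:
                tgt = tuple(max(target, s) for s in spacing)
                ds = vol_mod.downsample_volume(vol, tgt)
                dpath = volumes_dir / f"{config.brain_id}_{ch}_{target:g}um.nii.gz"
                vol_mod.write_nifti(ds, dpath)
                manifest.checksums[dpath.name] = _sha256(dpath)
                manifest.outputs[ch][f"nifti_{target:g}um"] = str(dpath)
            store = volumes_dir / f"{config.brain_id}_{ch}.ome.zarr"
            vol_mod.write_ome_zarr(vol, store, n_levels=config.n_levels,
                                   exposure=config.exposure_percentiles)
            manifest.checksums[store.name] = _tree_sha256(store)
            url = vol_mod.viewer_url(store, host=config.viewer_host,
                                     layer_name=f"{config.brain_id}_{ch}")
            manifest.outputs[ch]["ome_zarr"] = str(store)
            manifest.outputs[ch]["viewer_url"] = url
    finally:
        manifest.timings_s["total"] = round(time.perf_counter() - t_start, 4)
        manifest.write(manifest_path)
    return manifest
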