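"""Acquisition metadata and tile I/O.

A brain acquisition lives in a directory tree::

    <root>/<brain_id>/
        brain_volume.txt          # brain-volume metadata (key: value dialect)
        0000/                     # one folder per section
            section_metadata.txt
            <brain_id>_S0000_R00_C00_<channel>.tif
            ...

Metadata files are UTF-8 text, one ``key: value`` per line, ``#`` starts a
comment.  Tile files are single-plane grayscale TIFF (16-bit unsigned by
default).  Tiles that are expected by the grid layout but absent on disk are
flagged ``missing`` and load as all-zero placeholder images so the rest of
the pipeline never sees a hole.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import tifffile

__all__ = [
    "BrainVolumeMetadata",
    "SectionMetadata",
    "TileRecord",
    "Tile",
    "MetadataParseError",
    "parse_brain_metadata",
    "serialize_brain_metadata",
    "parse_section_metadata",
    "serialize_section_metadata",
    "read_brain_metadata",
    "read_section_metadata",
    "tile_filename",
    "section_dirname",
    "enumerate_tiles",
    "load_tile",
    "group_by_section",
]

BRAIN_METADATA_FILENAME = "brain_volume.txt"
SECTION_METADATA_FILENAME = "section_metadata.txt"


class MetadataParseError(ValueError):
    """Raised when a metadata text file violates the key:value dialect."""


@dataclass(frozen=True)
class BrainVolumeMetadata:
    """Whole-acquisition layout: grid shape, tile size, channels, spacing.

    ``tiles_per_row`` is the number of tiles along a row (i.e. the column
    count); ``tiles_per_col`` is the number of rows.  An 11 x 14 acquisition
    has ``tiles_per_col=11, tiles_per_row=14``.
    """

    brain_id: str
    n_sections: int
    tiles_per_row: int
    tiles_per_col: int
    tile_height_px: int
    tile_width_px: int
    n_channels: int
    channel_names: tuple[str, ...]
    nominal_overlap_px: int = 0
    in_plane_spacing_um: float = 1.25
    section_spacing_um: float = 50.0

    def __post_init__(self) -> None:
        for name in ("n_sections", "tiles_per_row", "tiles_per_col",
                     "tile_height_px", "tile_width_px", "n_channels"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_channels != len(self.channel_names):
            raise ValueError(
                f"n_channels={self.n_channels} but {len(self.channel_names)} "
                f"channel names given")
        if self.nominal_overlap_px >= min(self.tile_height_px, self.tile_width_px):
            raise ValueError("nominal_overlap_px must be smaller than the tile")
        if self.in_plane_spacing_um <= 0 or self.section_spacing_um <= 0:
            raise ValueError("spacings must be positive")

    @property
    def tiles_per_section_per_channel(self) -> int:
        return self.tiles_per_row * self.tiles_per_col

    @property
    def tiles_per_section(self) -> int:
        return self.tiles_per_section_per_channel * self.n_channels

    @property
    def n_tile_records(self) -> int:
        return self.n_sections * self.tiles_per_section


@dataclass(frozen=True)
class SectionMetadata:
    """Per-section stitching canvas description."""

    section_index: int
    canvas_height_px: int
    canvas_width_px: int
    tiles_per_row: int
    tiles_per_col: int
    n_channels: int
    margin_px: int = 0

    def __post_init__(self) -> None:
        if self.section_index < 0:
            raise ValueError("section_index must be >= 0")
        if self.canvas_height_px <= 0 or self.canvas_width_px <= 0:
            raise ValueError("canvas dimensions must be positive")
        if self.tiles_per_row <= 0 or self.tiles_per_col <= 0:
            raise ValueError("tile counts must be positive")
        if self.margin_px < 0:
            raise ValueError("margin_px must be >= 0")


@dataclass(frozen=True)
class TileRecord:
    """One expected tile file: identity within the grid plus a missing flag."""

    file_path: str
    section_index: int
    row: int
    col: int
    channel: str
    missing: bool


@dataclass
class Tile:
    """Pixel payload plus its record.  ``pixels`` is row-major, y-down."""

    pixels: np.ndarray
    record: TileRecord


# ---------------------------------------------------------------------------
# text dialect

_BRAIN_REQUIRED = {
    "brain_id": str,
    "n_sections": int,
    "tiles_per_row": int,
    "tiles_per_col": int,
    "tile_height_px": int,
    "tile_width_px": int,
    "n_channels": int,
    "channel_names": "channels",
}
_BRAIN_OPTIONAL = {
    "nominal_overlap_px": (int, 0),
    "in_plane_spacing_um": (float, 1.25),
    "section_spacing_um": (float, 50.0),
}

_SECTION_REQUIRED = {
    "section_index": int,
    "canvas_height_px": int,
    "canvas_width_px": int,
    "tiles_per_row": int,
    "tiles_per_col": int,
    "n_channels": int,
}
_SECTION_OPTIONAL = {"margin_px": (int, 0)}


def _parse_kv(text: str) -> dict[str, tuple[str, int]]:
    """Parse the dialect into {key: (raw value, line number)}."""
    out: dict[str, tuple[str, int]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise MetadataParseError(
                f"line {lineno}: expected 'key: value', got {raw!r}")
        key, value = line.split(":", 1)
        out[key.strip()] = (value.strip(), lineno)
    return out


def _convert(key: str, raw: str, lineno: int, conv) -> object:
    if conv == "channels":
        names = tuple(s.strip() for s in raw.split(",") if s.strip())
        if not names:
            raise MetadataParseError(f"line {lineno}: empty channel list")
        return names
    if conv is str:
        return raw
    try:
        if conv is int:
            return int(raw)
        return float(raw)
    except ValueError as exc:
        raise MetadataParseError(
            f"line {lineno}: malformed number for {key!r}: {raw!r}") from exc


def _parse(text: str, required: Mapping, optional: Mapping) -> dict:
    kv = _parse_kv(text)
    fields: dict[str, object] = {}
    for key, conv in required.items():
        if key not in kv:
            raise MetadataParseError(f"missing required key: {key!r}")
        raw, lineno = kv[key]
        fields[key] = _convert(key, raw, lineno, conv)
    for key, (conv, default) in optional.items():
        if key in kv:
            raw, lineno = kv[key]
            fields[key] = _convert(key, raw, lineno, conv)
        else:
            fields[key] = default
    return fields


def parse_brain_metadata(text: str) -> BrainVolumeMetadata:
    """Parse brain-volume metadata text into a :class:`BrainVolumeMetadata`.

    Raises :class:`MetadataParseError` naming the offending key or line.
    """
    return BrainVolumeMetadata(**_parse(text, _BRAIN_REQUIRED, _BRAIN_OPTIONAL))


def parse_section_metadata(text: str) -> SectionMetadata:
    return SectionMetadata(**_parse(text, _SECTION_REQUIRED, _SECTION_OPTIONAL))


def serialize_brain_metadata(meta: BrainVolumeMetadata) -> str:
    d = asdict(meta)
    d["channel_names"] = ", ".join(meta.channel_names)
    lines = ["# brain volume metadata"]
    lines += [f"{k}: {v}" for k, v in d.items()]
    return "\n".join(lines) + "\n"


def serialize_section_metadata(meta: SectionMetadata) -> str:
    lines = ["# section metadata"]
    lines += [f"{k}: {v}" for k, v in asdict(meta).items()]
    return "\n".join(lines) + "\n"


def read_brain_metadata(brain_dir: str | Path) -> BrainVolumeMetadata:
    path = Path(brain_dir) / BRAIN_METADATA_FILENAME
    return parse_brain_metadata(path.read_text())


def read_section_metadata(brain_dir: str | Path, section_index: int) -> SectionMetadata:
    path = Path(brain_dir) / section_dirname(section_index) / SECTION_METADATA_FILENAME
    return parse_section_metadata(path.read_text())


# ---------------------------------------------------------------------------
# tile hierarchy

def section_dirname(section_index: int) -> str:
    return f"{section_index:04d}"


def tile_filename(brain_id: str, section_index: int, row: int, col: int,
                  channel: str) -> str:
    """Canonical tile file name: ``<brain>_S0007_R03_C10_<channel>.tif``."""
    return f"{brain_id}_S{section_index:04d}_R{row:02d}_C{col:02d}_{channel}.tif"


def enumerate_tiles(root_path: str | Path,
                    brain_meta: BrainVolumeMetadata) -> list[TileRecord]:
    """Enumerate every expected tile of the acquisition.

    Returns exactly ``n_sections * tiles_per_col * tiles_per_row * n_channels``
    records sorted by (section, row, col, channel position), with
    ``missing=True`` for files absent on disk.
    """
    brain_dir = Path(root_path) / brain_meta.brain_id
    if not brain_dir.is_dir():
        raise FileNotFoundError(f"brain directory not found: {brain_dir}")
    records: list[TileRecord] = []
    for s in range(brain_meta.n_sections):
        sec_dir = brain_dir / section_dirname(s)
        present: set[str] = set(os.listdir(sec_dir)) if sec_dir.is_dir() else set()
        for r in range(brain_meta.tiles_per_col):
            for c in range(brain_meta.tiles_per_row):
                for ch in brain_meta.channel_names:
                    fname = tile_filename(brain_meta.brain_id, s, r, c, ch)
                    records.append(TileRecord(
                        file_path=str(sec_dir / fname),
                        section_index=s, row=r, col=c, channel=ch,
                        missing=fname not in present))
    return records


def load_tile(record: TileRecord, brain_meta: BrainVolumeMetadata) -> Tile:
    """Load one tile; a missing record yields an all-zero placeholder."""
    shape = (brain_meta.tile_height_px, brain_meta.tile_width_px)
    if record.missing:
        return Tile(pixels=np.zeros(shape, dtype=np.uint16), record=record)
    pixels = tifffile.imread(record.file_path)
    if pixels.shape != shape:
        raise ValueError(
            f"tile {record.file_path} has shape {pixels.shape}, "
            f"expected {shape} from brain metadata")
    return Tile(pixels=pixels, record=record)


def group_by_section(records: Iterable[TileRecord]) -> dict[int, list[TileRecord]]:
    """Partition records by section; each group sorted by (row, col, channel)."""
    groups: dict[int, list[TileRecord]] = {}
    for rec in records:
        groups.setdefault(rec.section_index, []).append(rec)
    for recs in groups.values():
        recs.sort(key=lambda r: (r.row, r.col, r.channel))
    return groups
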