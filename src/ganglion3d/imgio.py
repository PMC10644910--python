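"""Image and table I/O for the pipeline.

All images travel as multi-page grayscale TIFF with axis order (z, y, x),
plane 0 = first page.  Multi-channel stacks are stored plane-interleaved
(page order z0c0, z0c1, z1c0, ...) with channel names supplied by the run
manifest.  Instance label maps are written as 32-bit TIFF whose voxel
values are the exact integer labels (ImageJ-compatible: its native 32-bit
type is float, which represents integers exactly below 2**24).

Voxel spacing (µm) is embedded via ImageJ-style metadata on write and
recovered on read; a stack without spacing metadata defaults to (1, 1, 1)
with a warning, and downstream physical-unit outputs are then voxel-unit.
"""

from __future__ import annotations

import fnmatch
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger(__name__)

#: categorical codes used in RegionMap grids
BACKGROUND = 0
NSRR = 1
FRR = 2

REGION_NAMES = {BACKGROUND: "BACKGROUND", NSRR: "NSRR", FRR: "FRR"}

_MAX_EXACT_FLOAT32_INT = 2 ** 24


class ManifestError(ValueError):
    """Raised when a manifest file violates the documented dialect."""


@dataclass
class MultiChannelStack:
    """Named 3D intensity grids sharing one shape and voxel spacing."""

    channels: dict[str, np.ndarray]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    source_name: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("stack must contain at least one channel")
        shapes = {a.shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels disagree on shape: {shapes}")
        shape = shapes.pop()
        if len(shape) != 3:
            raise ValueError(f"channels must be 3D (z,y,x), got shape {shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if any(not name for name in self.channels):
            raise ValueError("channel names must be non-empty")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class InstanceLabelMap:
    """3D integer grid; 0 = background, each positive value one cell."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.labels.ndim != 3:
            raise ValueError(f"label grid must be 3D, got {self.labels.ndim}D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError(f"label grid must be integer-typed, got {self.labels.dtype}")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("label values must be >= 0")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def object_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_objects(self) -> int:
        return int(self.object_ids.size)


@dataclass
class RegionMap:
    """Hard partition of the volume into BACKGROUND / NSRR / FRR."""

    regions: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.regions.ndim != 3:
            raise ValueError("region grid must be 3D")
        bad = np.setdiff1d(np.unique(self.regions), [BACKGROUND, NSRR, FRR])
        if bad.size:
            raise ValueError(f"region grid holds unknown categories {bad.tolist()}")


_REQUIRED_MANIFEST_KEYS = {"channels", "target"}
_OPTIONAL_MANIFEST_KEYS = {
    "backend",
    "probmap_pattern",
    "region_source",
    "region_pattern",
    "input_pattern",
}
_BACKENDS = {"otsu", "probmap"}
_REGION_SOURCES = {"none", "probmap", "labelmap"}


@dataclass
class Manifest:
    """Parsed run manifest: channel naming plus backend selection.

    The manifest is a plain-text, line-oriented ``key: value`` document
    (a YAML-compatible subset).  Documented keys::

        channels: [iba1, dapi]        # required; names raw channels in order
        target: iba1                  # required; channel to segment
        backend: otsu | probmap       # default otsu
        probmap_pattern: <glob>       # required when backend is probmap
        region_source: none | probmap | labelmap   # default none
        region_pattern: <glob>        # required unless region_source is none
        input_pattern: <glob>         # which files are raw stacks; default *_stack.tif

    Unknown keys are rejected — a misspelled key must not silently fall
    back to a default.
    """

    channel_names: list[str]
    target_channel: str
    backend: str = "otsu"
    probmap_pattern: str = ""
    region_source: str = "none"
    region_pattern: str = ""
    input_pattern: str = "*_stack.tif"

    def __post_init__(self) -> None:
        if not self.channel_names:
            raise ManifestError("manifest must name at least one channel")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ManifestError(f"duplicate channel names: {self.channel_names}")
        if self.target_channel not in self.channel_names:
            raise ManifestError(
                f"target {self.target_channel!r} not among channels {self.channel_names}"
            )
        if self.backend not in _BACKENDS:
            raise ManifestError(f"unknown backend {self.backend!r}; expected one of {sorted(_BACKENDS)}")
        if self.backend == "probmap" and not self.probmap_pattern:
            raise ManifestError("backend 'probmap' requires a non-empty probmap_pattern")
        if self.region_source not in _REGION_SOURCES:
            raise ManifestError(
                f"unknown region_source {self.region_source!r}; expected one of {sorted(_REGION_SOURCES)}"
            )
        if self.region_source != "none" and not self.region_pattern:
            raise ManifestError(f"region_source {self.region_source!r} requires a region_pattern")


def parse_manifest(path: str | Path) -> Manifest:
    """Parse and validate a manifest file.

    Strict: required keys must be present, unknown keys are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ManifestError(f"manifest {path} is not valid key: value text: {exc}") from exc
    if not isinstance(raw, dict):
        raise ManifestError(f"manifest {path} must be a key: value mapping, got {type(raw).__name__}")

    keys = set(raw)
    unknown = keys - _REQUIRED_MANIFEST_KEYS - _OPTIONAL_MANIFEST_KEYS
    if unknown:
        raise ManifestError(f"manifest {path} has unknown key(s): {sorted(unknown)}")
    missing = _REQUIRED_MANIFEST_KEYS - keys
    if missing:
        raise ManifestError(f"manifest {path} missing required key(s): {sorted(missing)}")

    channels = raw["channels"]
    if isinstance(channels, str):
        channels = [c.strip() for c in channels.split(",")]
    if not isinstance(channels, list) or not all(isinstance(c, str) for c in channels):
        raise ManifestError("'channels' must be a list of names")

    kwargs = {
        "channel_names": channels,
        "target_channel": str(raw["target"]),
    }
    for key, attr in [
        ("backend", "backend"),
        ("probmap_pattern", "probmap_pattern"),
        ("region_source", "region_source"),
        ("region_pattern", "region_pattern"),
        ("input_pattern", "input_pattern"),
    ]:
        if key in raw:
            kwargs[attr] = str(raw[key])
    return Manifest(**kwargs)


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    """Serialize a manifest back to the documented text dialect."""
    lines = [
        f"channels: [{', '.join(manifest.channel_names)}]",
        f"target: {manifest.target_channel}",
        f"backend: {manifest.backend}",
    ]
    if manifest.probmap_pattern:
        lines.append(f"probmap_pattern: '{manifest.probmap_pattern}'")
    lines.append(f"region_source: {manifest.region_source}")
    if manifest.region_pattern:
        lines.append(f"region_pattern: '{manifest.region_pattern}'")
    lines.append(f"input_pattern: '{manifest.input_pattern}'")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# TIFF helpers
# ---------------------------------------------------------------------------

def _spacing_from_tiff(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    """Recover (z,y,x) spacing from ImageJ/shaped metadata + resolution tags."""
    meta = tif.imagej_metadata or {}
    if not meta and tif.shaped_metadata:
        meta = tif.shaped_metadata[0]
    z = meta.get("spacing")
    page = tif.pages[0]
    ytag = page.tags.get("YResolution")
    xtag = page.tags.get("XResolution")

    def _res(tag):
        if tag is None:
            return None
        num, den = tag.value
        return den / num if num else None

    y, x = _res(ytag), _res(xtag)
    if z is None or y is None or x is None:
        return None
    return (float(z), float(y), float(x))


def _write_tiff(array: np.ndarray, path: Path, spacing: tuple[float, float, float]) -> None:
    # tifffile's shaped format: a plain multi-page TIFF (ImageJ-openable)
    # whose JSON description preserves the exact array shape, so degenerate
    # axes survive a round trip; spacing rides in the description + tags
    z, y, x = spacing
    tifffile.imwrite(
        path,
        array,
        photometric="minisblack",
        resolution=(1.0 / x, 1.0 / y),
        metadata={"spacing": z, "unit": "um"},
    )


def read_stack(path: str | Path, manifest: Manifest) -> MultiChannelStack:
    """Read a multi-page TIFF into a named multi-channel stack.

    Page layout must be consistent with ``len(manifest.channel_names)``:
    either a plain z-stack (single channel), a plane-interleaved stack
    whose page count is divisible by the channel count, or an explicit
    4D (z, c, y, x) hyperstack.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack not found: {path}")
    n_chan = len(manifest.channel_names)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        spacing = _spacing_from_tiff(tif)
    if spacing is None:
        spacing = (1.0, 1.0, 1.0)
        warnings.warn(
            f"{path.name}: no voxel-spacing metadata; assuming isotropic (1,1,1) — "
            "physical-unit outputs are in voxel units",
            stacklevel=2,
        )

    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim == 3:
        n_pages = data.shape[0]
        if n_chan == 1:
            planes = data[:, np.newaxis]
        elif n_pages % n_chan == 0:
            planes = data.reshape(n_pages // n_chan, n_chan, *data.shape[1:])
        else:
            raise ValueError(
                f"{path.name}: {n_pages} pages not divisible by {n_chan} "
                f"channels named in manifest"
            )
    elif data.ndim == 4:
        if data.shape[1] == n_chan:
            planes = data
        elif data.shape[0] == n_chan:
            planes = np.moveaxis(data, 0, 1)
        else:
            raise ValueError(
                f"{path.name}: 4D shape {data.shape} does not match "
                f"{n_chan} channels named in manifest"
            )
    else:
        raise ValueError(f"{path.name}: unsupported TIFF dimensionality {data.ndim}")

    channels = {
        name: np.ascontiguousarray(planes[:, i])
        for i, name in enumerate(manifest.channel_names)
    }
    return MultiChannelStack(channels=channels, spacing=spacing, source_name=path.name)


def write_stack(stack: MultiChannelStack, path: str | Path) -> None:
    """Write a stack as a plane-interleaved multi-page TIFF (z0c0, z0c1, ...)."""
    arrays = list(stack.channels.values())
    interleaved = np.stack(arrays, axis=1)  # (z, c, y, x)
    nz, nc, ny, nx = interleaved.shape
    pages = interleaved.reshape(nz * nc, ny, nx)
    _write_tiff(pages, Path(path), stack.spacing)


def write_label_map(m: InstanceLabelMap, path: str | Path) -> None:
    """Write an instance label map as a 32-bit multi-page TIFF.

    Values are stored as float32 holding exact integers (the ImageJ
    32-bit convention); read-back reproduces the label grid exactly.
    """
    if m.labels.size and m.labels.max() >= _MAX_EXACT_FLOAT32_INT:
        raise ValueError(
            f"labels up to {int(m.labels.max())} exceed exact float32 range ({_MAX_EXACT_FLOAT32_INT})"
        )
    _write_tiff(m.labels.astype(np.float32), Path(path), m.spacing)


def read_label_map(path: str | Path) -> InstanceLabelMap:
    """Read a label map written by :func:`write_label_map` (or any integer TIFF)."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        spacing = _spacing_from_tiff(tif) or (1.0, 1.0, 1.0)
    if data.ndim == 2:
        data = data[np.newaxis]
    labels = np.rint(data).astype(np.int32)
    if not np.allclose(data, labels):
        raise ValueError(f"{path.name}: voxel values are not integral labels")
    return InstanceLabelMap(labels=labels, spacing=spacing)


def read_probmap(path: str | Path) -> np.ndarray:
    """Read a probability map, rescaling integer exports to [0, 1].

    8-/16-bit TIFFs are divided by their dtype maximum; float inputs are
    required to already lie in [0, 1].
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[np.newaxis]
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / np.iinfo(data.dtype).max
    else:
        data = data.astype(np.float64)
        if data.size and (data.min() < 0 or data.max() > 1):
            raise ValueError(f"{path.name}: float probability map outside [0,1]")
    return data


def write_region_map(r: RegionMap, path: str | Path) -> None:
    _write_tiff(r.regions.astype(np.uint8), Path(path), r.spacing)


def read_region_map(path: str | Path) -> RegionMap:
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        spacing = _spacing_from_tiff(tif) or (1.0, 1.0, 1.0)
    if data.ndim == 2:
        data = data[np.newaxis]
    return RegionMap(regions=data.astype(np.uint8), spacing=spacing)


def write_cell_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the annotated per-cell spreadsheet as UTF-8 CSV.

    One row per cell; the column set is produced by
    :func:`ganglion3d.quantify.quantify_objects` and always starts with
    (source_name, object_id, cell_class).
    """
    table.to_csv(path, index=False, encoding="utf-8")


def find_companion(stack_path: Path, pattern: str) -> Path:
    """Resolve a probmap/region companion file for a stack.

    ``pattern`` may contain ``{stem}`` (replaced by the stack filename
    minus its suffix, minus a trailing ``_stack``) or be a glob matched
    inside the stack's directory.
    """
    stem = stack_path.stem
    if stem.endswith("_stack"):
        stem = stem[: -len("_stack")]
    if "{stem}" in pattern:
        candidate = stack_path.parent / pattern.format(stem=stem)
        if not candidate.exists():
            raise FileNotFoundError(f"companion file {candidate} not found for {stack_path.name}")
        return candidate
    matches = sorted(
        p for p in stack_path.parent.iterdir()
        if fnmatch.fnmatch(p.name, pattern) and stem in p.stem
    )
    if not matches:
        raise FileNotFoundError(
            f"no file matching {pattern!r} with stem {stem!r} in {stack_path.parent}"
        )
    return matches[0]
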