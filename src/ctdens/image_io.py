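"""Reading and writing CT slices, series, masks and density distributions.

Two on-disk formats are supported for image series:

``fixture``
    A directory with a ``series.json`` manifest and one plain-text integer
    grid per slice (``np.savetxt`` style).  Grids hold Hounsfield Units
    directly.  This is the format the synthetic phantom generator and the
    CLI write; round-trips are bit exact.

``dicom``
    Single-frame CT DICOM files (read-only, via pydicom).  Raw stored values
    are converted to Hounsfield Units with the standard affine rescale
    ``HU = raw * RescaleSlope + RescaleIntercept``.  Slices are ordered
    vertex -> caudal by the z component of ImagePositionPatient (descending),
    ties broken by InstanceNumber.

HU values are stored as integers throughout; fractional rescale results are
rounded half-away-from-zero because downstream densitometry bins by integer
HU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

from .errors import FixtureFormatError, InvalidMetadataError

__all__ = [
    "CTSlice",
    "CTSeries",
    "to_hounsfield",
    "read_series",
    "write_series",
    "write_distribution",
    "read_distribution",
    "write_mask",
    "read_mask",
]

_MANIFEST = "series.json"


@dataclass(frozen=True)
class CTSlice:
    """One axial CT image: an integer HU grid plus spacing metadata.

    Coordinates are 0-based and row-major; masks produced elsewhere in the
    package share this frame.  ``slice_index`` counts from the vertex (0)
    toward the caudal end.
    """

    pixels: np.ndarray
    pixel_spacing: tuple[float, float] = (0.49, 0.49)
    slice_index: int = 0
    source_id: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("pixels must be a non-empty 2-D grid")
        if not np.issubdtype(px.dtype, np.integer):
            if not np.all(np.isfinite(px)):
                raise ValueError("HU values must be finite")
            if not np.all(px == np.round(px)):
                raise ValueError("HU values must be integers; rescale first")
            px = px.astype(np.int32)
        object.__setattr__(self, "pixels", px.astype(np.int32, copy=False))

    @property
    def rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def cols(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class CTSeries:
    """An ordered stack of axial slices from one examination."""

    slices: tuple[CTSlice, ...]
    subject_id: str = ""

    def __post_init__(self):
        slices = tuple(self.slices)
        if len(slices) < 1:
            raise ValueError("a series needs at least one slice")
        shape = slices[0].pixels.shape
        if any(s.pixels.shape != shape for s in slices):
            raise FixtureFormatError("mixed grid sizes within one series")
        object.__setattr__(self, "slices", slices)

    @property
    def n(self) -> int:
        """Number of images in the examination."""
        return len(self.slices)


def to_hounsfield(raw: np.ndarray, slope: float, intercept: float) -> np.ndarray:
    """Affine conversion of raw stored values to integer Hounsfield Units.

    Rounds half-away-from-zero so that e.g. ``-0.5 -> -1`` and ``0.5 -> 1``.
    """
    if slope == 0:
        raise InvalidMetadataError("RescaleSlope must be nonzero")
    v = np.asarray(raw, dtype=np.float64) * float(slope) + float(intercept)
    out = np.sign(v) * np.floor(np.abs(v) + 0.5)
    return out.astype(np.int32)


def write_series(series: CTSeries, path: str | Path) -> Path:
    """Write a series in the fixture format (manifest + one text grid per slice)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    entries = []
    for s in series.slices:
        fname = f"slice_{s.slice_index:03d}.txt"
        np.savetxt(path / fname, s.pixels, fmt="%d")
        entries.append(
            {
                "file": fname,
                "slice_index": s.slice_index,
                "pixel_spacing": list(s.pixel_spacing),
                "source_id": s.source_id,
            }
        )
    manifest = {"subject_id": series.subject_id, "slices": entries}
    (path / _MANIFEST).write_text(json.dumps(manifest, indent=1))
    return path


def _read_fixture(path: Path) -> CTSeries:
    mpath = path / _MANIFEST
    if not mpath.exists():
        raise FixtureFormatError(f"missing manifest {mpath}")
    manifest = json.loads(mpath.read_text())
    slices = []
    for entry in manifest["slices"]:
        fpath = path / entry["file"]
        try:
            grid = np.loadtxt(fpath, dtype=np.int64, ndmin=2)
        except OSError as exc:
            raise FixtureFormatError(f"unreadable slice file {fpath}") from exc
        slices.append(
            CTSlice(
                pixels=grid.astype(np.int32),
                pixel_spacing=tuple(entry.get("pixel_spacing", (0.49, 0.49))),
                slice_index=int(entry["slice_index"]),
                source_id=entry.get("source_id", ""),
            )
        )
    slices.sort(key=lambda s: s.slice_index)
    return CTSeries(slices=tuple(slices), subject_id=manifest.get("subject_id", ""))


def _read_dicom(path: Path) -> CTSeries:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file() and p.name != _MANIFEST)
    loaded = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception as exc:  # pydicom raises various parse errors
            raise FixtureFormatError(f"unreadable DICOM file {f}") from exc
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        hu = to_hounsfield(ds.pixel_array, slope, intercept)
        z = float(getattr(ds, "ImagePositionPatient", [0, 0, 0])[2])
        inst = int(getattr(ds, "InstanceNumber", 0))
        spacing = getattr(ds, "PixelSpacing", [0.49, 0.49])
        loaded.append((z, inst, hu, (float(spacing[0]), float(spacing[1])), f.name))
    if not loaded:
        raise FixtureFormatError(f"no DICOM files found under {path}")
    # vertex (superior, largest z) first, ties by acquisition order
    loaded.sort(key=lambda t: (-t[0], t[1]))
    slices = tuple(
        CTSlice(pixels=hu, pixel_spacing=spacing, slice_index=i, source_id=name)
        for i, (_z, _inst, hu, spacing, name) in enumerate(loaded)
    )
    return CTSeries(slices=slices, subject_id=path.name)


def read_series(path: str | Path, format: Literal["fixture", "dicom"] = "fixture") -> CTSeries:
    """Read a CT series from disk; HU conversion is already applied on return."""
    path = Path(path)
    if not path.exists():
        raise FixtureFormatError(f"no such path: {path}")
    if format == "fixture":
        return _read_fixture(path)
    if format == "dicom":
        return _read_dicom(path)
    raise ValueError(f"unknown format {format!r}")


def write_distribution(dist, path: str | Path) -> Path:
    """Serialize an 80-bin density distribution as CSV (columns hu, proportion)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["hu,proportion"]
    for hu, p in enumerate(dist.proportions):
        lines.append(f"{hu},{float(p)!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_distribution(path: str | Path, level: str = "series"):
    """Read a distribution written by :func:`write_distribution`."""
    from .densitometry import DensityDistribution

    path = Path(path)
    rows = path.read_text().strip().splitlines()
    if rows[0].strip() != "hu,proportion":
        raise FixtureFormatError(f"{path} is not a distribution file")
    props = np.zeros(80)
    for row in rows[1:]:
        hu_s, p_s = row.split(",")
        props[int(hu_s)] = float(p_s)
    return DensityDistribution(proportions=props, level=level)


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a binary mask as a portable 0/1 text grid."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, np.asarray(mask, dtype=np.uint8), fmt="%d")
    return path


def read_mask(path: str | Path) -> np.ndarray:
    return np.loadtxt(Path(path), dtype=np.int64, ndmin=2).astype(bool)
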