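"""Tracer-concentration volumes.

A whole-body PET study is represented as a 3D grid ``C(i, j, k)`` of
quantized tracer concentrations in ``[0, 255]``.  The first two axes are the
in-plane (transaxial) pixel axes and the last axis is the axial
slice-stacking axis.  All heterogeneity measures in this package operate on
this grid in index space: voxels are treated as unit cubes and the physical
voxel spacing (typically 2 x 2 x 4 mm for whole-body FDG protocols) is
carried along as metadata only.

Volumes can be built from a DICOM series (one file per axial slice), from a
plain-text container (see :func:`save_tcv` / :func:`load_tcv`) or directly
from arrays (phantoms).
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, replace
from pathlib import Path
import numpy as np

from .errors import VolumeLoadError

__all__ = [
    "Stage",
    "TracerVolume",
    "OccupancyMask",
    "apply_threshold",
    "crop_axial",
    "total_mass",
    "from_dicom_series",
    "save_tcv",
    "load_tcv",
]

MAX_VALUE = 255.0


class Stage(enum.IntEnum):
    """Longitudinal study stage j: before treatment, after two and after
    four therapy cycles."""

    BASELINE = 1
    INTERIM = 2
    FINAL = 3


@dataclass(frozen=True)
class TracerVolume:
    """A 3D tracer-concentration grid with acquisition metadata.

    Parameters
    ----------
    data
        3D array of concentrations, every value finite and in ``[0, 255]``.
        Stored as float64: integer-quantized for clinical volumes, but
        phantom measures may keep exact (unrounded) mass fractions.
    spacing
        Per-axis voxel size in millimetres.
    subject_id, stage, provenance
        Study metadata. ``stage`` is ``None`` for single-study subjects
        (healthy controls); ``provenance`` records how the grid was made
        (``"dicom"``, ``"raw"`` or ``"phantom"``).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    subject_id: str | None = None
    stage: Stage | None = None
    provenance: str = "raw"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 3:
            raise ValueError(f"volume must be 3D, got {arr.ndim} dimensions")
        if min(arr.shape) < 1:
            raise ValueError(f"all grid dimensions must be >= 1, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("volume contains non-finite values")
        if arr.min() < 0 or arr.max() > MAX_VALUE:
            raise ValueError(
                f"values must lie in [0, {MAX_VALUE:g}]; "
                f"got range [{arr.min():g}, {arr.max():g}]"
            )
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "spacing", spacing)
        if self.stage is not None:
            object.__setattr__(self, "stage", Stage(self.stage))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def total_mass(self) -> float:
        return float(self.data.sum())


@dataclass(frozen=True)
class OccupancyMask:
    """Boolean occupancy grid obtained by thresholding a volume at w."""

    mask: np.ndarray
    threshold_w: float

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        m.setflags(write=False)
        object.__setattr__(self, "mask", m)

    @property
    def count(self) -> int:
        """Number of occupied voxels."""
        return int(np.count_nonzero(self.mask))


def apply_threshold(volume: TracerVolume, w: float) -> OccupancyMask:
    """Mark voxels carrying a meaningful tracer signal: ``C >= w``.

    The default clinical threshold w = 1 keeps every nonzero quantized
    voxel, so even the faintest recorded concentrations (possible tiny
    metastases) contribute to the occupancy set; w = 0 marks every voxel.
    """
    if w < 0:
        raise ValueError(f"threshold w must be >= 0, got {w}")
    return OccupancyMask(volume.data >= w, float(w))


def crop_axial(volume: TracerVolume, lo_slice: int, hi_slice: int) -> TracerVolume:
    """Return the sub-volume of axial slices ``[lo_slice, hi_slice)``.

    Used to exclude regions of constitutively high glucose uptake — in the
    clinical protocol the brain — so that only the body from nose to toes
    enters the measures. Bounds are 0-based and half-open; metadata is
    preserved and the input is left unmodified.
    """
    n = volume.shape[2]
    if not (0 <= lo_slice < hi_slice <= n):
        raise ValueError(
            f"invalid axial crop [{lo_slice}, {hi_slice}) for extent {n}: "
            "need 0 <= lo < hi <= extent"
        )
    return replace(volume, data=volume.data[:, :, lo_slice:hi_slice])


def total_mass(volume: TracerVolume) -> float:
    """Sum of all voxel concentrations (the total tracer signal)."""
    return volume.total_mass()


# ---------------------------------------------------------------------------
# DICOM loading
# ---------------------------------------------------------------------------

def _rescale(arr: np.ndarray, policy: str) -> np.ndarray:
    if policy == "none":
        if arr.min() < 0 or arr.max() > MAX_VALUE:
            raise VolumeLoadError(
                "rescale policy 'none' requires stored values already in "
                f"[0, {MAX_VALUE:g}]; got [{arr.min():g}, {arr.max():g}]"
            )
        return arr
    if policy == "minmax":
        lo, hi = float(arr.min()), float(arr.max())
        if hi == lo:
            # a constant positive study maps to full scale, an empty one to 0
            return np.full_like(arr, MAX_VALUE if hi > 0 else 0.0)
        return np.rint((arr - lo) / (hi - lo) * MAX_VALUE)
    raise ValueError(f"unknown rescale policy {policy!r} (use 'minmax' or 'none')")


def from_dicom_series(
    directory: str | os.PathLike,
    rescale: str = "minmax",
    subject_id: str | None = None,
    stage: Stage | None = None,
) -> TracerVolume:
    """Stack one DICOM series (one file per axial slice) into a volume.

    Slices are ordered by ascending axial position (``ImagePositionPatient``
    z when present, else ``InstanceNumber``); per-slice ``RescaleSlope`` /
    ``RescaleIntercept`` are applied before quantization.  The default
    policy maps the study-wide minimum to 0 and maximum to 255 with integer
    rounding; ``"none"`` keeps stored values (phantom round-trips).
    """
    import pydicom

    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"DICOM directory not found: {directory}")
    paths = sorted(p for p in directory.iterdir() if p.is_file())
    if not paths:
        raise FileNotFoundError(f"no files in DICOM directory: {directory}")

    slices = []
    for path in paths:
        try:
            ds = pydicom.dcmread(path)
        except Exception as exc:  # pragma: no cover - malformed input path
            raise VolumeLoadError(f"cannot read DICOM slice {path.name}: {exc}") from exc
        slices.append((path, ds))

    rows, cols = slices[0][1].Rows, slices[0][1].Columns
    for path, ds in slices:
        if (ds.Rows, ds.Columns) != (rows, cols):
            raise VolumeLoadError(
                f"inconsistent slice dimensions in {path.name}: "
                f"{ds.Rows}x{ds.Columns} vs {rows}x{cols}"
            )

    def zpos(item):
        path, ds = item
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None and len(ipp) == 3:
            return float(ipp[2])
        return float(getattr(ds, "InstanceNumber", 0))

    slices.sort(key=zpos)
    planes = []
    for path, ds in slices:
        plane = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(plane * slope + intercept)
    arr = np.stack(planes, axis=-1)
    arr = _rescale(arr, rescale)

    ds0 = slices[0][1]
    px = getattr(ds0, "PixelSpacing", [1.0, 1.0])
    zs = [zpos(item) for item in slices]
    if len(zs) > 1 and zs[-1] != zs[0]:
        dz = abs(zs[1] - zs[0])
    else:
        dz = float(getattr(ds0, "SliceThickness", 1.0) or 1.0)
    spacing = (float(px[0]), float(px[1]), float(dz))
    return TracerVolume(
        arr, spacing=spacing, subject_id=subject_id, stage=stage, provenance="dicom"
    )


# ---------------------------------------------------------------------------
# Plain-text volume container (.tcv)
# ---------------------------------------------------------------------------

_TCV_MAGIC = "TCV1"


def save_tcv(volume: TracerVolume, path: str | os.PathLike) -> None:
    """Write a volume to the portable text container.

    Format: a ``TCV1`` magic line, ``key: value`` header lines (shape,
    spacing, subject, stage, provenance), a blank line, then the voxel
    values whitespace-separated in C order.  Lossless for float64 values
    (full repr precision).
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{_TCV_MAGIC}\n")
        fh.write("shape: {} {} {}\n".format(*volume.shape))
        fh.write("spacing: {:.17g} {:.17g} {:.17g}\n".format(*volume.spacing))
        fh.write(f"subject: {volume.subject_id or ''}\n")
        fh.write(f"stage: {int(volume.stage) if volume.stage is not None else ''}\n")
        fh.write(f"provenance: {volume.provenance}\n")
        fh.write("\n")
        flat = volume.data.ravel()
        for start in range(0, flat.size, 8):
            fh.write(" ".join(f"{v:.17g}" for v in flat[start : start + 8]))
            fh.write("\n")


def load_tcv(path: str | os.PathLike) -> TracerVolume:
    """Read a volume written by :func:`save_tcv`."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"volume container not found: {path}")
    with path.open() as fh:
        magic = fh.readline().strip()
        if magic != _TCV_MAGIC:
            raise VolumeLoadError(f"{path}: not a {_TCV_MAGIC} container (got {magic!r})")
        header: dict[str, str] = {}
        for line in fh:
            line = line.strip()
            if not line:
                break
            key, _, value = line.partition(":")
            header[key.strip()] = value.strip()
        try:
            shape = tuple(int(t) for t in header["shape"].split())
            spacing = tuple(float(t) for t in header["spacing"].split())
        except (KeyError, ValueError) as exc:
            raise VolumeLoadError(f"{path}: malformed header ({exc})") from exc
        try:
            values = np.array(fh.read().split(), dtype=float)
        except ValueError as exc:
            raise VolumeLoadError(f"{path}: malformed voxel data ({exc})") from exc
    if values.size != int(np.prod(shape)):
        raise VolumeLoadError(
            f"{path}: expected {int(np.prod(shape))} values for shape {shape}, "
            f"got {values.size}"
        )
    stage = Stage(int(header["stage"])) if header.get("stage") else None
    return TracerVolume(
        values.reshape(shape),
        spacing=spacing,  # type: ignore[arg-type]
        subject_id=header.get("subject") or None,
        stage=stage,
        provenance=header.get("provenance", "raw"),
    )
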