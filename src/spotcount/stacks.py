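"""3D image stack container and TIFF/CSV file I/O.

Coordinate convention used everywhere in this package: arrays are indexed
``(z, y, x)`` with 0-based integer voxel indices; ``z`` is the TIFF page
index and ``(y, x)`` are (row, column) within a page.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack",
    "GroundTruth",
    "read_stack",
    "write_stack",
    "read_truth",
    "write_truth",
    "ValidationError",
    "UnsupportedFormatError",
]

MIN_PLANE_SIDE = 32

TRUTH_COLUMNS = ["stack_id", "z", "y", "x", "magnitude"]


class ValidationError(ValueError):
    """Invalid parameters or malformed inputs."""


class UnsupportedFormatError(ValidationError):
    """Image file is not a single-channel unsigned-integer TIFF stack."""


@dataclass
class ImageStack:
    """A single-channel 3D fluorescence volume.

    Parameters
    ----------
    voxels
        Float array of shape ``(nz, ny, nx)`` with non-negative intensities.
    pixel_size_xy, z_step
        Physical size of one pixel / one plane step, in arbitrary length
        units. Only carried as metadata; all analysis works in voxel units.
    stack_id
        Opaque identifier propagated into every output table.
    """

    voxels: np.ndarray
    pixel_size_xy: float = 1.0
    z_step: float = 1.0
    stack_id: str = "stack"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValidationError("voxels must be a 3D (z, y, x) array")
        nz, ny, nx = self.voxels.shape
        if nz < 1 or ny < MIN_PLANE_SIDE or nx < MIN_PLANE_SIDE:
            raise ValidationError(
                f"stack must have >=1 plane of >= {MIN_PLANE_SIDE}x{MIN_PLANE_SIDE} "
                f"pixels, got {self.voxels.shape}"
            )
        if np.any(self.voxels < 0) or not np.all(np.isfinite(self.voxels)):
            raise ValidationError("intensities must be finite and non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class GroundTruth:
    """Known point-source locations and magnitudes for a synthetic stack."""

    sources: list[tuple[int, int, int, float]] = field(default_factory=list)
    stack_id: str = "stack"

    def __post_init__(self) -> None:
        seen = set()
        for z, y, x, mag in self.sources:
            if mag <= 0:
                raise ValidationError("source magnitude must be > 0")
            if (z, y, x) in seen:
                raise ValidationError(f"duplicate source voxel {(z, y, x)}")
            seen.add((z, y, x))

    def coordinates(self) -> np.ndarray:
        """Integer ``(n, 3)`` array of (z, y, x) source voxels."""
        if not self.sources:
            return np.empty((0, 3), dtype=np.intp)
        return np.array([(z, y, x) for z, y, x, _ in self.sources], dtype=np.intp)

    def magnitudes(self) -> np.ndarray:
        return np.array([m for _, _, _, m in self.sources], dtype=np.float64)

    def validate_against(self, stack: ImageStack) -> None:
        nz, ny, nx = stack.shape
        for z, y, x, _ in self.sources:
            if not (0 <= z < nz and 0 <= y < ny and 0 <= x < nx):
                raise ValidationError(f"source {(z, y, x)} outside stack {stack.shape}")


def read_stack(path, stack_id: str | None = None) -> ImageStack:
    """Read a multi-page grayscale TIFF into an :class:`ImageStack`.

    Pages map to z-planes in file order. Only 8/16-bit unsigned single-sample
    TIFFs are accepted; intensities are promoted to float64 without rescaling.
    """
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            if page.samplesperpixel != 1:
                raise UnsupportedFormatError(
                    f"{path!s}: {page.samplesperpixel} samples/pixel; "
                    "need single-channel grayscale"
                )
            arr = tif.asarray()
    except UnsupportedFormatError:
        raise
    except Exception as exc:  # noqa: BLE001 - surface parse errors explicitly
        raise UnsupportedFormatError(f"cannot parse TIFF {path!s}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise UnsupportedFormatError(
            f"{path!s}: expected single-sample grayscale pages, got shape {arr.shape}"
        )
    if arr.dtype not in (np.uint8, np.uint16):
        raise UnsupportedFormatError(
            f"{path!s}: unsupported pixel type {arr.dtype}; need uint8 or uint16"
        )
    if stack_id is None:
        stack_id = _id_from_path(path)
    return ImageStack(voxels=arr.astype(np.float64), stack_id=stack_id)


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as multi-page uint16 TIFF (one page per z-plane).

    In-memory voxels stay float; clipping at 0 and quantization to uint16
    happen only here.
    """
    data = np.clip(np.round(stack.voxels), 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(path, data.astype(np.uint16))


def read_truth(path) -> list[GroundTruth]:
    """Read ground-truth CSV (``stack_id,z,y,x,magnitude``), one entry per stack."""
    df = pd.read_csv(path, comment="#")
    missing = set(TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"truth CSV missing columns {sorted(missing)}")
    out = []
    for sid, grp in df.groupby("stack_id", sort=False):
        sources = [
            (int(r.z), int(r.y), int(r.x), float(r.magnitude))
            for r in grp.itertuples()
        ]
        out.append(GroundTruth(sources=sources, stack_id=str(sid)))
    return out


def write_truth(truth: GroundTruth, path) -> None:
    rows = [
        {"stack_id": truth.stack_id, "z": z, "y": y, "x": x, "magnitude": m}
        for z, y, x, m in truth.sources
    ]
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, index=False)


def _id_from_path(path) -> str:
    import os

    base = os.path.basename(os.fspath(path))
    return base.rsplit(".", 1)[0]
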