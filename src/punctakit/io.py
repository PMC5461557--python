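"""Image-stack and puncta table I/O with explicit coordinate conventions.

Conventions (stated once here, relied on everywhere):

* In memory, a stack is a ``(z, y, x)`` array; voxel sizes are given as
  ``(dx, dy, dz)`` in micrometres.  Axial steps commonly differ from lateral
  pixel size (e.g. 1.4 um z-steps at 20x, 0.45 um at 60x), so all distances
  downstream are computed in physical micrometres, never in voxel indices.
* Voxel indices are 0-based and refer to the voxel CENTER; ``origin`` is the
  physical (x, y, z) position of the center of voxel ``(0, 0, 0)``.
* On disk, stacks are plain multi-page grayscale TIFFs accompanied by a
  sidecar JSON ``{"dx_um": ..., "dy_um": ..., "dz_um": ...}``.  Reading falls
  back to TIFF resolution tags plus ImageJ ``spacing`` if the sidecar is
  absent, and refuses to guess when neither source is present.
* Puncta tables are CSV with columns ``x_um, y_um, z_um, intensity, quality,
  channel``; the ``_um`` suffix is mandatory so that slice-index coordinates
  can never enter the pipeline unnoticed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import MetadataError, ParameterError, SchemaError, UnsupportedFormatError

__all__ = [
    "ImageStack",
    "PunctaSet",
    "read_stack",
    "write_stack",
    "read_puncta_csv",
    "write_puncta_csv",
    "voxel_to_physical",
    "physical_to_voxel",
]

PUNCTA_COLUMNS = ("x_um", "y_um", "z_um", "intensity", "quality", "channel")


@dataclass
class ImageStack:
    """A 3D grayscale volume with anisotropic voxel-size metadata.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Non-negative intensities in (z, y, x) axis order.
    voxel_size : tuple of float
        ``(dx_um, dy_um, dz_um)``, all strictly positive.
    origin : tuple of float
        Physical (x, y, z) position in um of the center of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ParameterError(
                f"stack must be 3D (z, y, x); got {self.voxels.ndim} dimensions"
            )
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ParameterError(f"voxel sizes must be positive: {self.voxel_size}")
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def extent_um(self) -> tuple[float, float, float]:
        """Physical (x, y, z) extent covered by the voxel grid."""
        nz, ny, nx = self.voxels.shape
        dx, dy, dz = self.voxel_size
        return (nx * dx, ny * dy, nz * dz)


@dataclass
class PunctaSet:
    """Detected or simulated puncta as a physical-space point cloud.

    Coordinates are in micrometres, columns (x, y, z).  ``quality`` lives on
    a 0-100 scale (100 = strongest detection in its stack); simulated points
    carry quality 100 by convention.
    """

    coords: np.ndarray
    intensity: np.ndarray | None = None
    quality: np.ndarray | None = None
    channel: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.size == 0:
            coords = coords.reshape(0, 3)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ParameterError(f"coords must be (n, 3); got shape {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ParameterError("puncta coordinates must be finite")
        self.coords = coords
        n = len(coords)
        if self.intensity is None:
            self.intensity = np.ones(n)
        self.intensity = np.asarray(self.intensity, dtype=float).reshape(n)
        if self.quality is None:
            self.quality = np.full(n, 100.0)
        self.quality = np.asarray(self.quality, dtype=float).reshape(n)
        if n and (self.quality.min() < 0 or self.quality.max() > 100):
            raise ParameterError("quality scores must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.coords)

    def with_channel(self, channel: str) -> "PunctaSet":
        return replace(self, channel=channel)


def voxel_to_physical(index, voxel_size, origin=(0.0, 0.0, 0.0)):
    """Convert a (k, j, i) = (z, y, x) voxel index to physical (x, y, z) um.

    Fractional (sub-voxel) indices are allowed.  The physical point is the
    voxel center: ``x = origin_x + i * dx`` and likewise for y, z.
    """
    index = np.asarray(index, dtype=float)
    dx, dy, dz = voxel_size
    k, j, i = index[..., 0], index[..., 1], index[..., 2]
    out = np.stack(
        [origin[0] + i * dx, origin[1] + j * dy, origin[2] + k * dz], axis=-1
    )
    return out


def physical_to_voxel(xyz, voxel_size, origin=(0.0, 0.0, 0.0)):
    """Inverse of :func:`voxel_to_physical`: physical (x, y, z) -> fractional (k, j, i)."""
    xyz = np.asarray(xyz, dtype=float)
    dx, dy, dz = voxel_size
    x, y, z = xyz[..., 0], xyz[..., 1], xyz[..., 2]
    return np.stack(
        [(z - origin[2]) / dz, (y - origin[1]) / dy, (x - origin[0]) / dx], axis=-1
    )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImageStack, path) -> Path:
    """Write a multi-page grayscale TIFF plus a voxel-size sidecar JSON."""
    path = Path(path)
    dx, dy, dz = stack.voxel_size
    tifffile.imwrite(
        path,
        stack.voxels,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "ZYX"},
        imagej=stack.voxels.dtype in (np.dtype("uint8"), np.dtype("uint16")),
    )
    sidecar = {
        "dx_um": dx,
        "dy_um": dy,
        "dz_um": dz,
        "origin_um": list(stack.origin),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_stack(path) -> ImageStack:
    """Read a multi-page grayscale TIFF with voxel-size metadata.

    Voxel size is taken from the sidecar JSON if present, otherwise from the
    TIFF resolution tags (lateral) plus ImageJ ``spacing`` (axial).  A stack
    without any voxel-size source raises :class:`MetadataError` rather than
    assuming a default: every downstream distance is physical.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise UnsupportedFormatError(
                f"{path.name}: expected a single-channel z-stack, got shape {arr.shape}"
            )
        page = tif.pages[0]
        if page.samplesperpixel != 1:
            raise UnsupportedFormatError(
                f"{path.name}: RGB/multi-sample TIFFs are not supported"
            )
        voxel_size = None
        origin = (0.0, 0.0, 0.0)
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            try:
                voxel_size = (
                    float(meta["dx_um"]),
                    float(meta["dy_um"]),
                    float(meta["dz_um"]),
                )
            except KeyError as exc:
                raise MetadataError(f"{sidecar.name}: missing key {exc}") from exc
            origin = tuple(meta.get("origin_um", origin))
        else:
            voxel_size = _voxel_size_from_tags(tif, page)
        if voxel_size is None:
            raise MetadataError(
                f"{path.name}: no voxel size in sidecar JSON or TIFF tags; "
                "refusing to assume one"
            )
    return ImageStack(arr, voxel_size, origin)


def _voxel_size_from_tags(tif, page):
    tags = page.tags
    xres = tags.get("XResolution")
    yres = tags.get("YResolution")
    spacing = None
    if tif.imagej_metadata:
        spacing = tif.imagej_metadata.get("spacing")
    if xres is None or yres is None or spacing is None:
        return None

    def _to_um(res):
        num, den = res.value
        if num == 0:
            return None
        return den / num  # pixels per unit -> unit per pixel

    dx, dy = _to_um(xres), _to_um(yres)
    if dx is None or dy is None:
        return None
    return (dx, dy, float(spacing))


def write_puncta_csv(puncta: PunctaSet, path) -> Path:
    """Write a puncta table; an empty set produces a header-only file."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "x_um": puncta.coords[:, 0],
            "y_um": puncta.coords[:, 1],
            "z_um": puncta.coords[:, 2],
            "intensity": puncta.intensity,
            "quality": puncta.quality,
            "channel": np.repeat(puncta.channel, len(puncta)),
        }
    )
    with open(path, "w") as fh:
        if puncta.provenance:
            fh.write(f"# provenance: {puncta.provenance}\n")
        df.to_csv(fh, index=False)
    return path


def read_puncta_csv(path) -> PunctaSet:
    """Read a puncta CSV, enforcing physical-unit (``_um``) coordinate columns."""
    path = Path(path)
    provenance = ""
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# provenance:"):
            provenance = first.removeprefix("# provenance:").strip()
        else:
            fh.seek(0)
        df = pd.read_csv(fh)
    missing = [c for c in ("x_um", "y_um", "z_um") if c not in df.columns]
    if missing:
        bare = [c for c in ("x", "y", "z") if c in df.columns]
        hint = (
            f" (found {bare}: coordinates must be physical um, suffixed _um)"
            if bare
            else ""
        )
        raise SchemaError(f"{path.name}: missing coordinate columns {missing}{hint}")
    coords = df[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    channel = ""
    if "channel" in df.columns and len(df):
        channel = str(df["channel"].iloc[0])
    return PunctaSet(
        coords,
        intensity=df["intensity"].to_numpy(float) if "intensity" in df else None,
        quality=df["quality"].to_numpy(float) if "quality" in df else None,
        channel=channel,
        provenance=provenance,
    )
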