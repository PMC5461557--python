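"""Laminar intensity profiles across cortical layers.

A laminar profile is the mean fluorescence intensity as a function of
position along one axis (typically cortical depth), averaged over the band
of voxels orthogonal to it, and optionally normalized so that a reference
(background) layer — conventionally Layer I — has mean 1.  Normalized
profiles are what developmental intensity time courses are built from.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import ImageStack

__all__ = [
    "IntensityProfile",
    "laminar_profile",
    "normalize_profile",
    "profile_timecourse",
]

_AXIS_TO_DIM = {"z": 0, "y": 1, "x": 2}  # memory order (z, y, x)
_AXIS_TO_VS = {"x": 0, "y": 1, "z": 2}  # voxel_size order (dx, dy, dz)


@dataclass
class IntensityProfile:
    """positions_um: bin centers along the laminar axis (strictly
    increasing); mean_intensity: band-averaged intensity per bin;
    background_value: the reference mean divided out when normalized."""

    positions_um: np.ndarray
    mean_intensity: np.ndarray
    axis: str = "y"
    normalized: bool = False
    background_value: float | None = None

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.mean_intensity = np.asarray(self.mean_intensity, dtype=float)
        if len(self.positions_um) != len(self.mean_intensity):
            raise ParameterError("positions and intensities must have equal length")
        if len(self.positions_um) > 1 and np.any(np.diff(self.positions_um) <= 0):
            raise ParameterError("positions must be strictly increasing")


def laminar_profile(
    stack: ImageStack,
    axis: str = "y",
    band: dict | None = None,
    bin_um: float | None = None,
    reducer: str = "mean",
) -> IntensityProfile:
    """Band-averaged intensity along ``axis`` binned at ``bin_um``.

    ``band`` optionally restricts the orthogonal axes to physical intervals,
    e.g. ``{"x": (0, 20)}``.  ``bin_um`` defaults to the voxel size along
    the axis and may not be smaller.  ``reducer`` is ``mean`` (default,
    matching generic intensity measurement) or ``median``.
    """
    if axis not in _AXIS_TO_DIM:
        raise ParameterError(f"axis must be one of x, y, z; got {axis!r}")
    if reducer not in ("mean", "median"):
        raise ParameterError("reducer must be 'mean' or 'median'")
    dim = _AXIS_TO_DIM[axis]
    step = stack.voxel_size[_AXIS_TO_VS[axis]]
    if bin_um is None:
        bin_um = step
    if bin_um < step:
        raise ParameterError(f"bin_um ({bin_um}) must be >= voxel size along {axis} ({step})")

    vox = stack.voxels
    slicer = [slice(None)] * 3
    for other_axis, interval in (band or {}).items():
        if other_axis == axis:
            raise ParameterError("band restricts orthogonal axes, not the profile axis")
        odim = _AXIS_TO_DIM[other_axis]
        ostep = stack.voxel_size[_AXIS_TO_VS[other_axis]]
        o0 = stack.origin[_AXIS_TO_VS[other_axis]]
        lo, hi = interval
        # voxels whose centers fall inside the interval
        i0 = max(0, int(np.ceil((lo - o0) / ostep)))
        i1 = min(vox.shape[odim], int(np.floor((hi - o0) / ostep)) + 1)
        if i1 <= i0:
            raise ParameterError(f"band {interval} on axis {other_axis!r} selects no voxels")
        slicer[odim] = slice(i0, i1)
    vox = vox[tuple(slicer)]
    if vox.size == 0:
        raise ParameterError("band selects an empty region")

    n_along = vox.shape[dim]
    origin_along = stack.origin[_AXIS_TO_VS[axis]]
    centers = origin_along + step * np.arange(n_along)
    extent = n_along * step
    n_bins = int(np.ceil(extent / bin_um))
    start = centers[0] - step / 2
    bin_idx = np.minimum(((centers - start) / bin_um).astype(int), n_bins - 1)

    moved = np.moveaxis(vox, dim, 0).reshape(n_along, -1)
    positions = []
    values = []
    for b in range(n_bins):
        rows = moved[bin_idx == b]
        if rows.size == 0:
            continue
        positions.append(start + (b + 0.5) * bin_um)
        values.append(float(np.mean(rows)) if reducer == "mean" else float(np.median(rows)))
    return IntensityProfile(np.array(positions), np.array(values), axis=axis)


def normalize_profile(profile: IntensityProfile, background_region) -> IntensityProfile:
    """Divide the whole profile by its mean over ``background_region``
    (a physical ``(lo, hi)`` interval along the profile axis).

    The background region's normalized mean is 1 by construction, so
    normalizing twice against the same region is the identity.
    """
    lo, hi = background_region
    mask = (profile.positions_um >= lo) & (profile.positions_um <= hi)
    if not np.any(mask):
        raise ParameterError(
            f"background region {background_region} contains no profile bins"
        )
    background = float(np.mean(profile.mean_intensity[mask]))
    if background <= 0:
        raise ParameterError(
            f"background mean is {background}; normalization requires a positive background"
        )
    return replace(
        profile,
        mean_intensity=profile.mean_intensity / background,
        normalized=True,
        background_value=background,
    )


def profile_timecourse(
    profiles: list[tuple[str, IntensityProfile]],
    interval: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Per-label peak and mean of normalized profiles, e.g. one profile per
    developmental time point.

    All profiles must share the same normalization state; ``interval``
    optionally restricts the summary to a physical sub-range.
    """
    if not profiles:
        raise ParameterError("need at least one labelled profile")
    flags = {p.normalized for _, p in profiles}
    if len(flags) > 1:
        raise ParameterError("profiles mix normalized and raw intensities")
    rows = []
    for label, prof in profiles:
        vals = prof.mean_intensity
        if interval is not None:
            lo, hi = interval
            mask = (prof.positions_um >= lo) & (prof.positions_um <= hi)
            if not np.any(mask):
                raise ParameterError(f"interval {interval} is outside profile {label!r}")
            vals = vals[mask]
        rows.append(
            {"label": label, "peak": float(vals.max()), "mean": float(vals.mean())}
        )
    return pd.DataFrame(rows).set_index("label")
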