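"""Synthetic inputs for the quantification pipeline.

Everything the pipeline consumes can be generated here with a fixed seed:
homogeneous-Poisson and Thomas-cluster point fields (the null and the
clustered alternative for friends-of-friends statistics), renderable
confocal-like anisotropic stacks, paired object sets with a prescribed
colocalization fraction, laminar intensity phantoms, and full two-hemisphere
multi-animal experiment designs with controllable treatment effects.

Coordinates are continuous physical micrometres throughout; voxelization
happens only in :func:`render_stack`.  All randomness flows through explicit
integer seeds — there is no global random state.

Default densities are chosen so that a 2 um linking length produces partial
clustering (some puncta clustered, some not), which is the regime where the
cluster-fraction statistic is informative; no measured density is implied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .errors import PackingError, ParameterError
from .io import ImageStack, PunctaSet

__all__ = [
    "VolumeSpec",
    "ThomasParams",
    "ExperimentDesign",
    "SimulatedSite",
    "simulate_poisson_points",
    "simulate_thomas_points",
    "render_stack",
    "gaussian_mass_in_box",
    "simulate_coloc_objects",
    "simulate_experiment",
    "simulate_laminar_phantom",
]

# Parents for the Thomas process are generated in a box padded by this many
# offspring sigmas so that clusters straddling the boundary are not depleted.
THOMAS_PARENT_PADDING_SIGMAS = 4.0


@dataclass(frozen=True)
class VolumeSpec:
    """Axis-aligned imaging volume, extents in micrometres."""

    extent_x_um: float
    extent_y_um: float
    extent_z_um: float

    def __post_init__(self) -> None:
        if min(self.extent_x_um, self.extent_y_um, self.extent_z_um) <= 0:
            raise ParameterError(f"volume extents must be positive: {self}")

    @property
    def extents(self) -> np.ndarray:
        return np.array([self.extent_x_um, self.extent_y_um, self.extent_z_um])

    @property
    def volume_um3(self) -> float:
        return float(np.prod(self.extents))


@dataclass(frozen=True)
class ThomasParams:
    """Thomas cluster process: Poisson parents, Gaussian-dispersed offspring.

    parent_intensity : parents per um^3
    mean_offspring   : expected offspring per parent (Poisson)
    offspring_sigma_um : isotropic Gaussian dispersion of offspring (um)
    """

    parent_intensity: float
    mean_offspring: float
    offspring_sigma_um: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.parent_intensity <= 0:
            raise ParameterError("parent_intensity must be > 0")
        if self.mean_offspring <= 0:
            raise ParameterError("mean_offspring must be > 0")
        if self.offspring_sigma_um <= 0:
            raise ParameterError("offspring_sigma_um must be > 0")

    @property
    def total_intensity(self) -> float:
        """Expected points per um^3 ignoring boundary losses."""
        return self.parent_intensity * self.mean_offspring


@dataclass(frozen=True)
class ExperimentDesign:
    """Two-hemisphere, multi-section, multi-site design for one cohort.

    Each animal contributes ``sections_per_hemisphere x sites_per_section``
    imaging sites per hemisphere.  The treated hemisphere's puncta density is
    multiplied by ``treatment_effect_count`` and its mean offspring per
    cluster by ``treatment_effect_clustering``; factors of 1 mean no effect.
    A lognormal per-animal multiplier on the base density (sd
    ``animal_sd``) models inter-animal variability in staining/expression,
    which is what control-hemisphere normalization is meant to remove.
    """

    n_animals: int
    sections_per_hemisphere: int = 2
    sites_per_section: int = 3
    treatment_effect_count: float = 1.0
    treatment_effect_clustering: float = 1.0
    animal_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ParameterError("n_animals must be >= 1")
        if self.sections_per_hemisphere < 1 or self.sites_per_section < 1:
            raise ParameterError("sections and sites per section must be >= 1")
        if self.treatment_effect_count <= 0 or self.treatment_effect_clustering <= 0:
            raise ParameterError("treatment effect factors must be > 0")
        if self.animal_sd < 0:
            raise ParameterError("animal_sd must be >= 0")


@dataclass
class SimulatedSite:
    """One simulated imaging site with its design labels."""

    animal_id: str
    hemisphere: str  # "control" or "treated"
    section_id: int
    site_id: int
    puncta: PunctaSet


def simulate_poisson_points(intensity: float, volume: VolumeSpec, seed: int) -> PunctaSet:
    """Homogeneous Poisson point field: ``count ~ Poisson(intensity * V)``,
    coordinates uniform in the box."""
    if intensity < 0:
        raise ParameterError("intensity must be >= 0")
    rng = np.random.default_rng(seed)
    n = rng.poisson(intensity * volume.volume_um3)
    coords = rng.uniform(0.0, 1.0, size=(n, 3)) * volume.extents
    return PunctaSet(coords, provenance=f"poisson(intensity={intensity}, seed={seed})")


def simulate_thomas_points(params: ThomasParams, volume: VolumeSpec) -> PunctaSet:
    """Thomas cluster field inside ``volume``.

    Parents are drawn in a box padded by ``THOMAS_PARENT_PADDING_SIGMAS``
    offspring sigmas on every side so clusters near the boundary are not
    systematically depleted; offspring falling outside the volume are
    discarded, so the realized count is at most
    ``parent_intensity * V_padded * mean_offspring`` in expectation and close
    to ``parent_intensity * V * mean_offspring`` when sigma << extents.
    """
    rng = np.random.default_rng(params.seed)
    pad = THOMAS_PARENT_PADDING_SIGMAS * params.offspring_sigma_um
    lo = -pad
    hi = volume.extents + pad
    padded_volume = float(np.prod(hi - lo))
    n_parents = rng.poisson(params.parent_intensity * padded_volume)
    parents = rng.uniform(0.0, 1.0, size=(n_parents, 3)) * (hi - lo) + lo
    n_offspring = rng.poisson(params.mean_offspring, size=n_parents)
    centers = np.repeat(parents, n_offspring, axis=0)
    pts = centers + rng.normal(0.0, params.offspring_sigma_um, size=centers.shape)
    inside = np.all((pts >= 0.0) & (pts <= volume.extents), axis=1)
    return PunctaSet(
        pts[inside],
        provenance=(
            f"thomas(parent_intensity={params.parent_intensity}, "
            f"mean_offspring={params.mean_offspring}, "
            f"sigma={params.offspring_sigma_um}, seed={params.seed})"
        ),
    )


def gaussian_mass_in_box(
    center, sigma, extents, voxel_volume: float, peak: float = 1.0
) -> float:
    """Analytic integral of a peak-normalized anisotropic Gaussian inside the
    box [0, extents], expressed in summed-voxel units (integral / voxel
    volume).  Used by the renderer's conservation-of-mass checks."""
    center = np.asarray(center, float)
    sigma = np.asarray(sigma, float)
    extents = np.asarray(extents, float)
    fracs = 0.5 * (
        special.erf((extents - center) / (np.sqrt(2) * sigma))
        - special.erf((0.0 - center) / (np.sqrt(2) * sigma))
    )
    full_mass = peak * float(np.prod(np.sqrt(2 * np.pi) * sigma))
    return full_mass * float(np.prod(fracs)) / voxel_volume


def render_stack(
    points: PunctaSet,
    volume: VolumeSpec,
    voxel_size=(0.2, 0.2, 0.45),
    psf_sigma_um=(0.3, 0.3, 0.6),
    peak_intensity: float = 1000.0,
    noise: str = "none",
    noise_sd: float = 0.0,
    seed: int | None = None,
    out_of_bounds: str = "clip",
) -> ImageStack:
    """Render puncta as anisotropy-aware 3D Gaussian blobs into a voxel grid.

    The grid tiles ``volume`` with voxel centers at half-voxel offsets, so
    voxel (0,0,0) sits at ``(dx/2, dy/2, dz/2)``.  Each punctum adds a
    separable Gaussian of per-axis sigma ``psf_sigma_um`` and amplitude
    ``peak_intensity * punctum.intensity`` (simulated intensities default
    to 1).  ``noise`` is one of ``none``, ``poisson`` (shot noise on the
    expected counts) or ``gaussian`` (additive, sd ``noise_sd``, clipped at
    zero).  ``out_of_bounds`` controls points outside the volume: ``clip``
    drops them, ``error`` raises.
    """
    dx, dy, dz = (float(v) for v in voxel_size)
    if min(dx, dy, dz) <= 0:
        raise ParameterError("voxel sizes must be positive")
    sx, sy, sz = (float(v) for v in psf_sigma_um)
    if min(sx, sy, sz) <= 0:
        raise ParameterError("psf sigmas must be positive")
    if noise not in ("none", "poisson", "gaussian"):
        raise ParameterError(f"unknown noise model {noise!r}")
    if out_of_bounds not in ("clip", "error"):
        raise ParameterError("out_of_bounds must be 'clip' or 'error'")

    ex, ey, ez = volume.extents
    nx, ny, nz = (int(math.ceil(e / d)) for e, d in zip((ex, ey, ez), (dx, dy, dz)))
    stack = np.zeros((nz, ny, nx), dtype=float)
    origin = (dx / 2, dy / 2, dz / 2)

    coords = points.coords
    outside = np.any((coords < 0) | (coords > volume.extents), axis=1)
    if np.any(outside):
        if out_of_bounds == "error":
            raise ParameterError(
                f"{int(outside.sum())} puncta lie outside the volume"
            )
        coords = coords[~outside]
        amps = points.intensity[~outside]
    else:
        amps = points.intensity

    # Each blob is added over a +/-5 sigma window; the truncated tail is
    # below 3e-6 of the blob mass, well inside the renderer's 1% mass budget.
    half = 5.0
    xs = origin[0] + dx * np.arange(nx)
    ys = origin[1] + dy * np.arange(ny)
    zs = origin[2] + dz * np.arange(nz)
    for (px, py, pz), amp in zip(coords, amps):
        i0, i1 = _window(px, sx * half, xs)
        j0, j1 = _window(py, sy * half, ys)
        k0, k1 = _window(pz, sz * half, zs)
        gx = np.exp(-0.5 * ((xs[i0:i1] - px) / sx) ** 2)
        gy = np.exp(-0.5 * ((ys[j0:j1] - py) / sy) ** 2)
        gz = np.exp(-0.5 * ((zs[k0:k1] - pz) / sz) ** 2)
        stack[k0:k1, j0:j1, i0:i1] += (
            peak_intensity * amp * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        )

    if noise == "poisson":
        rng = np.random.default_rng(seed)
        stack = rng.poisson(stack).astype(float)
    elif noise == "gaussian":
        rng = np.random.default_rng(seed)
        stack = np.clip(stack + rng.normal(0.0, noise_sd, size=stack.shape), 0.0, None)

    return ImageStack(stack, (dx, dy, dz), origin)


def _window(center: float, reach: float, axis_coords: np.ndarray) -> tuple[int, int]:
    lo = int(np.searchsorted(axis_coords, center - reach, side="left"))
    hi = int(np.searchsorted(axis_coords, center + reach, side="right"))
    return lo, hi


def simulate_coloc_objects(
    n_a: int,
    n_b: int,
    overlap_fraction: float,
    match_radius_um: float,
    volume: VolumeSpec,
    seed: int,
    max_attempts: int = 20000,
):
    """Paired object sets with an exact, constructed colocalization fraction.

    Exactly ``round(n_a * overlap_fraction)`` A objects are placed strictly
    within ``match_radius_um`` of a distinct B object; every other A-B pair
    is separated by more than twice the match radius, so centroid matching
    at that radius recovers the requested fraction exactly in both
    directions.  B objects are kept at pairwise separation > 3 radii so a
    matched A can never fall inside a second B's radius.

    Raises :class:`PackingError` if the separation constraints cannot be
    satisfied at the requested density (too many objects for the volume).
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ParameterError("overlap_fraction must be in [0, 1]")
    if match_radius_um <= 0:
        raise ParameterError("match_radius_um must be > 0")
    n_matched = round(n_a * overlap_fraction)
    if n_matched > n_b:
        raise ParameterError(
            f"round(n_a * overlap_fraction) = {n_matched} exceeds n_b = {n_b}"
        )
    from .coloc import ObjectSet  # local import: coloc does not import simulate

    rng = np.random.default_rng(seed)
    extents = volume.extents
    r = match_radius_um

    b_pts = _place_separated(rng, n_b, extents, 3.0 * r, max_attempts)

    a_pts = np.empty((n_a, 3))
    # Matched A: uniform in the ball of radius 0.9 r around its own B.
    for idx in range(n_matched):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        radius = 0.9 * r * rng.uniform() ** (1.0 / 3.0)
        a_pts[idx] = np.clip(b_pts[idx] + radius * direction, 0.0, extents)
        if np.linalg.norm(a_pts[idx] - b_pts[idx]) > r:  # clipping pushed it out
            a_pts[idx] = b_pts[idx]
    # Unmatched A: rejection-sample farther than 2 r from every B.
    for idx in range(n_matched, n_a):
        for _ in range(max_attempts):
            cand = rng.uniform(size=3) * extents
            if n_b == 0 or np.min(np.linalg.norm(b_pts - cand, axis=1)) > 2.0 * r:
                a_pts[idx] = cand
                break
        else:
            raise PackingError(
                "could not place a non-overlapping A object; volume too crowded "
                f"for match_radius={r} um"
            )
    return (
        ObjectSet(a_pts, marker="A"),
        ObjectSet(b_pts, marker="B"),
    )


def _place_separated(rng, n, extents, min_sep, max_attempts) -> np.ndarray:
    pts = np.empty((n, 3))
    for idx in range(n):
        for _ in range(max_attempts):
            cand = rng.uniform(size=3) * extents
            if idx == 0 or np.min(np.linalg.norm(pts[:idx] - cand, axis=1)) > min_sep:
                pts[idx] = cand
                break
        else:
            raise PackingError(
                f"could not place {n} objects at pairwise separation > {min_sep} um "
                f"in a {extents} um box"
            )
    return pts


def simulate_experiment(
    design: ExperimentDesign, base: ThomasParams, volume: VolumeSpec
) -> list[SimulatedSite]:
    """Simulate one cohort: a Thomas puncta field per (animal, hemisphere,
    section, site).

    The treated hemisphere's parent intensity is scaled by
    ``treatment_effect_count`` and its mean offspring by
    ``treatment_effect_clustering``; both hemispheres of an animal share that
    animal's lognormal density multiplier, so the treated/control ratio
    isolates the treatment effect.
    """
    rng = np.random.default_rng(design.seed)
    animal_effects = np.exp(
        rng.normal(0.0, design.animal_sd, size=design.n_animals)
        - 0.5 * design.animal_sd**2  # mean-one lognormal
    )
    sites: list[SimulatedSite] = []
    for a in range(design.n_animals):
        for hemisphere in ("control", "treated"):
            count_factor = (
                design.treatment_effect_count if hemisphere == "treated" else 1.0
            )
            clust_factor = (
                design.treatment_effect_clustering if hemisphere == "treated" else 1.0
            )
            for section in range(design.sections_per_hemisphere):
                for site in range(design.sites_per_section):
                    params = ThomasParams(
                        parent_intensity=base.parent_intensity
                        * animal_effects[a]
                        * count_factor,
                        mean_offspring=base.mean_offspring * clust_factor,
                        offspring_sigma_um=base.offspring_sigma_um,
                        seed=int(rng.integers(2**31)),
                    )
                    sites.append(
                        SimulatedSite(
                            animal_id=f"animal{a:02d}",
                            hemisphere=hemisphere,
                            section_id=section,
                            site_id=site,
                            puncta=simulate_thomas_points(params, volume),
                        )
                    )
    return sites


def simulate_laminar_phantom(
    layer_boundaries_um,
    layer_means,
    noise_sd: float = 0.0,
    voxel_size=(1.0, 1.0, 1.0),
    seed: int | None = None,
    extent_x_um: float = 20.0,
    extent_z_um: float = 5.0,
) -> ImageStack:
    """Cortical-depth phantom: expected intensity piecewise-constant along y.

    ``layer_boundaries_um`` are the full layer edges (length =
    ``len(layer_means) + 1``, strictly increasing); the stack spans
    ``[boundaries[0], boundaries[-1]]`` along y.  Gaussian noise of sd
    ``noise_sd`` is added per voxel and clipped at zero.
    """
    bounds = np.asarray(layer_boundaries_um, dtype=float)
    means = np.asarray(layer_means, dtype=float)
    if bounds.ndim != 1 or len(bounds) != len(means) + 1:
        raise ParameterError(
            "need len(layer_boundaries_um) == len(layer_means) + 1 (full edges)"
        )
    if np.any(np.diff(bounds) <= 0):
        raise ParameterError("layer boundaries must be strictly increasing")
    dx, dy, dz = (float(v) for v in voxel_size)
    ny = int(math.ceil((bounds[-1] - bounds[0]) / dy))
    nx = int(math.ceil(extent_x_um / dx))
    nz = int(math.ceil(extent_z_um / dz))
    y_centers = bounds[0] + dy / 2 + dy * np.arange(ny)
    layer_of_row = np.clip(np.searchsorted(bounds, y_centers, side="right") - 1, 0, len(means) - 1)
    profile = means[layer_of_row]
    stack = np.broadcast_to(profile[None, :, None], (nz, ny, nx)).astype(float).copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        stack = np.clip(stack + rng.normal(0.0, noise_sd, size=stack.shape), 0.0, None)
    origin = (dx / 2, bounds[0] + dy / 2, dz / 2)
    return ImageStack(stack, (dx, dy, dz), origin)
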