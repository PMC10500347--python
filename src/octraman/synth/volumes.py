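"""Synthetic OCT cell phantoms.

Cells are modelled as star-convex bodies: a sphere of radius ``radius_um``
whose radius function carries smooth Gaussian "protrusion" bumps at random
directions on the unit sphere,

    r(u) = radius + sum_i  a_i * exp(-angle(u, u_i)^2 / (2 * s^2)),

voxelised on an anisotropic grid.  Protrusion count and amplitude are the
dials for surface roughness and compactness; interior mean/SD set the
intensity features.  Glass-slide reflections are emulated as additive
uniform z-planes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ..types import GroundTruth, LabelMap, Volume3D

__all__ = [
    "SyntheticCellParams",
    "generate_cell_volume",
    "generate_multicell_volume",
    "add_reflection_planes",
    "generate_population",
]

#: angular half-width (radians) of a protrusion bump on the radius function
BUMP_ANGULAR_SIGMA = 0.30

#: overlapping bump contributions are capped at this multiple of the single-bump
#: amplitude, which bounds the maximal radius of the body independently of the
#: (random) bump directions
MAX_BUMP_STACK = 2.5


def _max_radius(params: "SyntheticCellParams") -> float:
    if params.protrusion_count == 0 or params.protrusion_amplitude_um == 0:
        return params.radius_um
    return params.radius_um + MAX_BUMP_STACK * params.protrusion_amplitude_um


@dataclass(frozen=True)
class SyntheticCellParams:
    """Generative knobs for a single synthetic cell."""

    radius_um: float
    protrusion_count: int = 0
    protrusion_amplitude_um: float = 0.0
    interior_mean: float = 100.0
    interior_sd: float = 0.0
    background_sd: float = 0.0
    center_um: tuple[float, float, float] | None = None  # (x, y, z); None = grid centre

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("radius_um must be > 0")
        if self.protrusion_amplitude_um < 0:
            raise ValueError("protrusion_amplitude_um must be >= 0")
        if self.protrusion_amplitude_um >= self.radius_um:
            raise ValueError("protrusion_amplitude_um must be < radius_um")
        if self.interior_sd < 0 or self.background_sd < 0:
            raise ValueError("intensity SDs must be >= 0")
        if self.protrusion_count < 0:
            raise ValueError("protrusion_count must be >= 0")


def _random_unit_vectors(n: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _cell_mask(
    params: SyntheticCellParams,
    spacing: tuple[float, float, float],
    shape: tuple[int, int, int],
    center_um: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Boolean occupancy of the star-convex cell on the voxel grid."""
    dx, dy, dz = spacing
    nz, ny, nx = shape
    # physical coordinates of voxel centres relative to the cell centre (x, y, z)
    zc = np.arange(nz) * dz - center_um[2]
    yc = np.arange(ny) * dy - center_um[1]
    xc = np.arange(nx) * dx - center_um[0]
    Z, Y, X = np.meshgrid(zc, yc, xc, indexing="ij")
    rho = np.sqrt(X * X + Y * Y + Z * Z)

    r_max = _max_radius(params)
    inside = rho <= params.radius_um  # core sphere
    if params.protrusion_count > 0 and params.protrusion_amplitude_um > 0:
        dirs = _random_unit_vectors(params.protrusion_count, rng)
        shell = (rho > params.radius_um) & (rho <= r_max)
        if np.any(shell):
            with np.errstate(invalid="ignore"):
                ux = X[shell] / rho[shell]
                uy = Y[shell] / rho[shell]
                uz = Z[shell] / rho[shell]
            bump = np.zeros(ux.shape)
            for d in dirs:
                cosang = np.clip(ux * d[0] + uy * d[1] + uz * d[2], -1.0, 1.0)
                ang = np.arccos(cosang)
                bump = bump + np.exp(-(ang**2) / (2.0 * BUMP_ANGULAR_SIGMA**2))
            bump = np.minimum(bump, MAX_BUMP_STACK)
            r_local = params.radius_um + params.protrusion_amplitude_um * bump
            inside[shell] = rho[shell] <= r_local
    return inside


def _check_fit(
    params: SyntheticCellParams,
    spacing: tuple[float, float, float],
    shape: tuple[int, int, int],
    center_um: np.ndarray,
) -> None:
    r_max = _max_radius(params)
    extents = {
        "x": (center_um[0], spacing[0] * (shape[2] - 1)),
        "y": (center_um[1], spacing[1] * (shape[1] - 1)),
        "z": (center_um[2], spacing[2] * (shape[0] - 1)),
    }
    for axis, (c, full) in extents.items():
        if c - r_max < 0 or c + r_max > full:
            raise ValueError(
                f"cell (max radius {r_max:.2f} µm at centre {c:.2f} µm) exceeds the "
                f"grid along {axis} (physical extent {full:.2f} µm)"
            )


def generate_cell_volume(
    params: SyntheticCellParams,
    spacing: tuple[float, float, float],
    shape: tuple[int, int, int],
    seed: int,
    class_label: str = "synthetic",
) -> tuple[Volume3D, GroundTruth]:
    """Voxelise one synthetic cell onto a noisy background.

    Interior voxels draw ``Normal(interior_mean, interior_sd)`` and background
    voxels ``Normal(0, background_sd)``, both clipped at zero.  Deterministic
    for a fixed seed.

    Returns the intensity volume and the ground truth (binary label map with
    the cell as object 1, plus its voxel-count volume and centroid).
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    dx, dy, dz = spacing
    if params.center_um is None:
        center = np.array(
            [dx * (nx - 1) / 2.0, dy * (ny - 1) / 2.0, dz * (nz - 1) / 2.0]
        )
    else:
        center = np.asarray(params.center_um, dtype=float)
    _check_fit(params, spacing, shape, center)

    mask = _cell_mask(params, spacing, shape, center, rng)

    data = np.clip(rng.normal(0.0, params.background_sd, size=shape), 0.0, None)
    n_in = int(mask.sum())
    interior = rng.normal(params.interior_mean, params.interior_sd, size=n_in)
    data[mask] = np.clip(interior, 0.0, None)

    vol = Volume3D(
        data,
        spacing,
        meta={"seed": int(seed), "class_label": class_label, "generator": "cell"},
    )
    labels = LabelMap(mask.astype(np.int32), spacing)
    voxvol = dx * dy * dz
    zc, yc, xc = (c.mean() for c in np.nonzero(mask))
    truth = GroundTruth(
        labels,
        [(1, class_label, n_in * voxvol, (float(xc * dx), float(yc * dy), float(zc * dz)))],
    )
    return vol, truth


def generate_multicell_volume(
    cells: list[tuple[SyntheticCellParams, str]],
    spacing: tuple[float, float, float],
    shape: tuple[int, int, int],
    seed: int,
    background_sd: float = 2.0,
) -> tuple[Volume3D, GroundTruth]:
    """Place several cells (each with an explicit ``center_um``) in one grid.

    Later cells overwrite earlier ones where masks would overlap; each cell
    receives a distinct ground-truth label in placement order.
    """
    rng = np.random.default_rng(seed)
    data = np.clip(rng.normal(0.0, background_sd, size=shape), 0.0, None)
    labels = np.zeros(shape, dtype=np.int32)
    records = []
    dx, dy, dz = spacing
    for i, (params, cls) in enumerate(cells, start=1):
        if params.center_um is None:
            raise ValueError(f"cell {i}: center_um must be explicit in a multi-cell grid")
        center = np.asarray(params.center_um, dtype=float)
        _check_fit(params, spacing, shape, center)
        mask = _cell_mask(params, spacing, shape, center, rng)
        n_in = int(mask.sum())
        data[mask] = np.clip(
            rng.normal(params.interior_mean, params.interior_sd, size=n_in), 0.0, None
        )
        labels[mask] = i
        zc, yc, xc = (c.mean() for c in np.nonzero(mask))
        records.append(
            (i, cls, n_in * dx * dy * dz, (float(xc * dx), float(yc * dy), float(zc * dz)))
        )
    vol = Volume3D(data, spacing, meta={"seed": int(seed), "generator": "multicell"})
    return vol, GroundTruth(LabelMap(labels, spacing), records)


def add_reflection_planes(
    volume: Volume3D, plane_indices: list[int], amplitude: float
) -> Volume3D:
    """Add a uniform offset to the listed z-slices, emulating the bright
    glass-slide reflection planes seen in FF-OCT stacks."""
    nz = volume.shape[0]
    for idx in plane_indices:
        if not (0 <= idx < nz):
            raise ValueError(f"plane index {idx} outside z range [0, {nz})")
    data = volume.data.copy()
    for idx in plane_indices:
        data[idx] += amplitude
    meta = dict(volume.meta)
    meta["reflection_planes"] = sorted(int(i) for i in plane_indices)
    return Volume3D(data, volume.spacing, meta)


def _draw_params(
    profile, rng: np.random.Generator
) -> SyntheticCellParams:
    """One parameter draw from a class profile's per-field distributions."""
    d = profile.param_distributions

    def draw(key: str, lo: float | None = None) -> float:
        mean, sd = d[key]
        v = rng.normal(mean, sd)
        if lo is not None:
            v = max(v, lo)
        return float(v)

    radius = draw("radius_um", lo=2.0)
    amp = draw("protrusion_amplitude_um", lo=0.0)
    amp = min(amp, 0.9 * radius)  # keep the star-convex invariant
    mean_c, sd_c = d["protrusion_count"]
    count = max(0, int(round(rng.normal(mean_c, sd_c))))
    return SyntheticCellParams(
        radius_um=radius,
        protrusion_count=count,
        protrusion_amplitude_um=amp,
        interior_mean=draw("interior_mean", lo=1.0),
        interior_sd=draw("interior_sd", lo=0.0),
        background_sd=draw("background_sd", lo=0.0),
    )


def generate_population(
    profiles: list,
    n_per_class: dict[str, int],
    spacing: tuple[float, float, float] = (0.45, 0.45, 0.2),
    seed: int = 0,
    margin_um: float = 1.5,
) -> list[tuple[Volume3D, GroundTruth]]:
    """Draw a labelled population of single-cell volumes, one grid per cell.

    Each cell's grid is sized to its own maximal radius plus ``margin_um`` on
    every side.  Deterministic for a fixed seed; per-cell seeds are derived
    from the master seed so volumes are independent.
    """
    by_label = {p.class_label: p for p in profiles}
    for label, n in n_per_class.items():
        if label not in by_label:
            raise ValueError(f"unknown class label {label!r}")
        if n < 1:
            raise ValueError(f"n_per_class[{label!r}] must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    out: list[tuple[Volume3D, GroundTruth]] = []
    dx, dy, dz = spacing
    for label in sorted(n_per_class):
        profile = by_label[label]
        for _ in range(n_per_class[label]):
            params = _draw_params(profile, rng)
            cell_seed = int(rng.integers(0, 2**31 - 1))
            half = _max_radius(params) + margin_um
            shape = (
                int(np.ceil(2 * half / dz)) + 1,
                int(np.ceil(2 * half / dy)) + 1,
                int(np.ceil(2 * half / dx)) + 1,
            )
            vol, truth = generate_cell_volume(
                params, spacing, shape, cell_seed, class_label=label
            )
            out.append((vol, truth))
    return out
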