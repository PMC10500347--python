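"""Per-cell morphometric and intensity features.

Five features per segmented cell, computed on the *unfiltered* volume:

* **V** — volume: foreground voxel count × voxel volume (µm³);
* **C** — compactness ``36·π·V² / A³``: 1 for a perfect sphere, decreasing
  with surface irregularity (sphericity ``Ψ = C^(1/3)`` is exposed too);
* **SR** — RMS surface roughness (Rq, µm): the top-surface height map
  ``z(x, y)`` takes the shallowest foreground voxel per lateral column, and
  SR is the population RMS deviation of the heights about their mean (the
  mean-absolute variant Ra is available via ``kind="ra"``);
* **AI** — mean interior intensity (a.u.);
* **IS** — population SD of interior intensity (a.u.).

Surface area (the auxiliary **A**) comes from a marching-cubes iso-surface
at 0.5 on the binary object — voxel-face counting would overestimate a
sphere's area by tens of percent and wreck compactness.  Internal holes are
filled per object before any computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure

from .types import GroundTruth, LabelMap, Volume3D

__all__ = [
    "CellFeatures",
    "FEATURE_NAMES",
    "cell_volume",
    "cell_surface_area",
    "compactness",
    "surface_roughness",
    "intensity_stats",
    "extract_features",
    "features_to_frame",
]

#: canonical feature order
FEATURE_NAMES = (
    "volume_um3",
    "compactness",
    "surface_roughness_um",
    "mean_intensity",
    "intensity_sd",
)


@dataclass
class CellFeatures:
    cell_id: int
    volume_um3: float
    compactness: float
    surface_roughness_um: float
    mean_intensity: float
    intensity_sd: float
    surface_area_um2: float
    class_label: str | None = None

    def __post_init__(self) -> None:
        if self.volume_um3 <= 0 or self.surface_area_um2 <= 0:
            raise ValueError("volume and surface area must be > 0")
        if self.intensity_sd < 0 or self.compactness <= 0:
            raise ValueError("intensity SD must be >= 0 and compactness > 0")


def _object_mask(labels: LabelMap, cell_id: int, fill: bool = True) -> np.ndarray:
    mask = labels.labels == cell_id
    if not mask.any():
        raise KeyError(f"cell id {cell_id} not present in label map")
    if fill:
        # fill internal holes; restricting to the bounding box is equivalent
        # (an internal hole never touches it) and much faster on large grids
        zs, ys, xs = np.nonzero(mask)
        sl = tuple(slice(int(a.min()), int(a.max()) + 1) for a in (zs, ys, xs))
        mask = mask.copy()
        mask[sl] = ndi.binary_fill_holes(mask[sl])
    return mask


def _mask_volume(mask: np.ndarray, spacing) -> float:
    dx, dy, dz = spacing
    return float(mask.sum()) * dx * dy * dz


def _mask_surface_area(
    mask: np.ndarray, spacing, smooth_um: float | None, cell_id: int
) -> float:
    dx, dy, dz = spacing
    if smooth_um is None:
        smooth_um = SURFACE_SMOOTH_FRAC * max(dx, dy, dz)
    zs, ys, xs = np.nonzero(mask)
    thin = min(
        int(zs.max() - zs.min()) + 1,
        int(ys.max() - ys.min()) + 1,
        int(xs.max() - xs.min()) + 1,
    )
    if thin < 2:
        import warnings

        warnings.warn(
            f"cell {cell_id} is one voxel thick along an axis; "
            "falling back to voxel-face surface area",
            UserWarning,
            stacklevel=3,
        )
        return _voxel_face_area(mask, (dz, dy, dx))
    sl = tuple(slice(int(a.min()), int(a.max()) + 1) for a in (zs, ys, xs))
    padded = np.pad(mask[sl].astype(np.float32), 4)
    if smooth_um > 0:
        padded = ndi.gaussian_filter(
            padded, (smooth_um / dz, smooth_um / dy, smooth_um / dx)
        )
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=(dz, dy, dx))
    return float(measure.mesh_surface_area(verts, faces))


def _mask_roughness(mask: np.ndarray, spacing, kind: str) -> float:
    dx, dy, dz = spacing
    footprint = mask.any(axis=0)
    first_z = np.argmax(mask, axis=0)  # valid only within the footprint
    heights = first_z[footprint] * dz
    dev = heights - heights.mean()
    if kind == "rq":
        return float(np.sqrt(np.mean(dev**2)))
    return float(np.mean(np.abs(dev)))


def cell_volume(labels: LabelMap, cell_id: int) -> float:
    """Voxel-count volume in µm³ (holes filled)."""
    return _mask_volume(_object_mask(labels, cell_id), labels.spacing)


#: Gaussian anti-alias width for iso-surfacing, as a fraction of the largest
#: voxel pitch.  Without smoothing, the staircase of the binarised surface
#: inflates a sphere's area by >10% at 0.45 µm lateral pitch; ~half that
#: pitch removes the staircase while keeping corner rounding of flat-faced
#: bodies below 5%.  Tying the width to the spacing keeps surface area
#: scaling exactly as s² under uniform spatial rescaling.
SURFACE_SMOOTH_FRAC = 0.49


def cell_surface_area(
    labels: LabelMap, cell_id: int, smooth_um: float | None = None
) -> float:
    """Iso-surface (marching cubes, level 0.5) area of the object in µm².

    The binary object is lightly Gaussian-smoothed (``smooth_um``, physical
    units) before extracting the iso-surface, suppressing voxelisation
    staircase.  Objects thinner than 2 voxels along some axis cannot carry a
    closed iso-surface; those fall back to the exposed voxel-face area, with
    a ``UserWarning`` emitted.
    """
    return _mask_surface_area(
        _object_mask(labels, cell_id), labels.spacing, smooth_um, cell_id
    )


def _voxel_face_area(mask: np.ndarray, sampling_zyx: tuple[float, float, float]) -> float:
    """Exposed-face area; fallback for one-voxel-thick degenerate objects."""
    dz, dy, dx = sampling_zyx
    face = {0: dy * dx, 1: dz * dx, 2: dz * dy}
    total = 0.0
    m = mask.astype(np.int8)
    for axis, a in face.items():
        d = np.diff(m, axis=axis)
        total += a * (np.abs(d).sum())
        # faces on the array boundary
        first = np.take(m, 0, axis=axis)
        last = np.take(m, -1, axis=axis)
        total += a * (first.sum() + last.sum())
    return float(total)


def compactness(volume_um3: float, surface_area_um2: float) -> float:
    """``C = 36·π·V²/A³`` — dimensionless, 1 for a sphere."""
    if volume_um3 <= 0 or surface_area_um2 <= 0:
        raise ValueError("volume and surface area must be > 0")
    return float(36.0 * np.pi * volume_um3**2 / surface_area_um2**3)


def surface_roughness(
    labels: LabelMap,
    cell_id: int,
    spacing: tuple[float, float, float] | None = None,
    kind: str = "rq",
) -> float:
    """Roughness of the top surface seen from above (z = 0 side).

    ``kind="rq"`` (default) is the RMS deviation of the column-wise top
    heights about their mean (population convention); ``kind="ra"`` is the
    mean absolute deviation.
    """
    if kind not in ("rq", "ra"):
        raise ValueError(f"unknown roughness kind {kind!r}")
    mask = _object_mask(labels, cell_id)
    return _mask_roughness(
        mask, spacing if spacing is not None else labels.spacing, kind
    )


def intensity_stats(
    volume: Volume3D, labels: LabelMap, cell_id: int
) -> tuple[float, float]:
    """Mean and population SD of the raw intensities inside the (filled)
    object mask."""
    if volume.shape != labels.labels.shape:
        raise ValueError(
            f"volume shape {volume.shape} does not match labels {labels.labels.shape}"
        )
    mask = _object_mask(labels, cell_id)
    vals = volume.data[mask]
    return float(vals.mean()), float(vals.std(ddof=0))


def extract_features(
    volume: Volume3D,
    labels: LabelMap,
    truth: GroundTruth | None = None,
) -> list[CellFeatures]:
    """One feature record per object, ordered by id.  When ground truth is
    supplied, class labels are joined by best voxel overlap."""
    if volume.shape != labels.labels.shape:
        raise ValueError("volume and label map are not aligned")
    rows: list[CellFeatures] = []
    truth_labels = None
    truth_classes: dict[int, str] = {}
    if truth is not None:
        truth_labels = truth.label_map.labels
        truth_classes = {int(r[0]): r[1] for r in truth.per_cell_truth}
    for cid in labels.ids:
        cid = int(cid)
        mask = _object_mask(labels, cid)  # filled once, reused by every feature
        v = _mask_volume(mask, labels.spacing)
        a = _mask_surface_area(mask, labels.spacing, None, cid)
        vals = volume.data[mask]
        mean_i, sd_i = float(vals.mean()), float(vals.std(ddof=0))
        cls = volume.meta.get("class_label")
        if truth_labels is not None:
            overlap = truth_labels[labels.labels == cid]
            overlap = overlap[overlap > 0]
            if overlap.size:
                cls = truth_classes.get(int(np.bincount(overlap).argmax()), cls)
        rows.append(
            CellFeatures(
                cell_id=cid,
                volume_um3=v,
                compactness=compactness(v, a),
                surface_roughness_um=_mask_roughness(mask, labels.spacing, "rq"),
                mean_intensity=mean_i,
                intensity_sd=sd_i,
                surface_area_um2=a,
                class_label=cls,
            )
        )
    return rows


def features_to_frame(
    rows: list[CellFeatures], volume_id: str | None = None
) -> pd.DataFrame:
    """Serialize feature records into the canonical table layout."""
    rec = [
        {
            "volume_id": volume_id,
            "cell_id": r.cell_id,
            "class_label": r.class_label,
            **{name: getattr(r, name) for name in FEATURE_NAMES},
            "surface_area_um2": r.surface_area_um2,
        }
        for r in rows
    ]
    cols = ["volume_id", "cell_id", "class_label", *FEATURE_NAMES, "surface_area_um2"]
    return pd.DataFrame(rec, columns=cols)
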