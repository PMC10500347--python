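"""Core in-memory containers shared across the pipeline.

Axis convention: volumetric arrays are indexed ``[z, y, x]`` with ``z = 0``
the shallowest slice (one TIFF page per z-slice).  Voxel spacing is carried
as ``(dx, dy, dz)`` in micrometres, i.e. in *coordinate* order, matching how
instrument metadata is usually reported.  All positions are voxel-centre,
0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["Volume3D", "LabelMap", "GroundTruth", "RamanSpectrum"]


@dataclass
class Volume3D:
    """A 3D scalar intensity grid with physical voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Nonnegative intensities in arbitrary units.
    spacing : tuple of float
        ``(dx, dy, dz)`` voxel pitch in µm; all components positive.
    meta : dict
        Free-form provenance (seed, class label, processing history...).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got {self.data.ndim}D")
        dx, dy, dz = self.spacing
        if min(dx, dy, dz) <= 0:
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    @property
    def sampling_zyx(self) -> tuple[float, float, float]:
        """Spacing reordered to array-axis order (dz, dy, dx)."""
        dx, dy, dz = self.spacing
        return (dz, dy, dx)


@dataclass
class LabelMap:
    """Integer-labelled segmentation aligned to a :class:`Volume3D`.

    Label 0 is background; object ids form the contiguous range ``1..K``.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected 3D labels, got {self.labels.ndim}D")
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be nonnegative")

    @property
    def ids(self) -> np.ndarray:
        """Sorted object ids present (excluding background)."""
        u = np.unique(self.labels)
        return u[u > 0]

    @property
    def n_objects(self) -> int:
        return int(self.ids.size)

    @property
    def sampling_zyx(self) -> tuple[float, float, float]:
        dx, dy, dz = self.spacing
        return (dz, dy, dx)


@dataclass
class GroundTruth:
    """Generator-side truth for a synthetic volume: the true label map plus
    per-cell records ``(cell_id, class_label, volume_um3, centroid_um)``."""

    label_map: LabelMap
    per_cell_truth: list[tuple[int, str, float, tuple[float, float, float]]]

    def __post_init__(self) -> None:
        ids_map = set(int(i) for i in self.label_map.ids)
        ids_rec = set(int(r[0]) for r in self.per_cell_truth)
        if ids_map != ids_rec:
            raise ValueError(
                f"ground-truth ids mismatch: map has {sorted(ids_map)}, "
                f"records have {sorted(ids_rec)}"
            )


@dataclass
class RamanSpectrum:
    """A Raman spectrum: strictly increasing wavenumber axis (cm⁻¹) and
    same-length nonnegative intensities (a.u.)."""

    wavenumber_cm1: np.ndarray
    intensity: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumber_cm1 = np.asarray(self.wavenumber_cm1, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.wavenumber_cm1.shape != self.intensity.shape:
            raise ValueError("axis and intensity lengths differ")
        if self.wavenumber_cm1.ndim != 1:
            raise ValueError("spectrum must be one-dimensional")
        if self.wavenumber_cm1.size >= 2 and not np.all(
            np.diff(self.wavenumber_cm1) > 0
        ):
            raise ValueError("wavenumber axis must be strictly increasing")

    def __len__(self) -> int:
        return int(self.wavenumber_cm1.size)
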