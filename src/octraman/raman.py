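"""Raman spectral preprocessing.

The chain mirrors standard cell-Raman practice: subtract the instrument
(Mirau objective) reference, estimate and remove the broad fluorescence
baseline, average the per-sample sweep replicates, crop to the analysis
window (600–2100 cm⁻¹) and assemble a full-spectrum feature matrix.

Baseline estimation defaults to asymmetric least squares (ALS): minimise
``Σ w_i (y_i − z_i)² + λ Σ (Δ²z)²`` with weights ``w_i = p`` above the
baseline and ``1 − p`` below, iterated to a fixed point.  λ controls
smoothness, the asymmetry ``p ≪ 0.5`` pins the baseline under the peaks.
An iteratively reweighted polynomial fit is available as an alternative.
No detector roll-off correction is applied; the rolled-off region stays in
the analysis window as acquired.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .types import RamanSpectrum

__all__ = [
    "BaselineConfig",
    "subtract_reference",
    "remove_fluorescence",
    "average_replicates",
    "crop_window",
    "resample",
    "to_feature_matrix",
]


@dataclass(frozen=True)
class BaselineConfig:
    method: str = "als"  # or "polynomial"
    als_lambda: float = 1e5
    als_p: float = 0.01
    poly_degree: int = 5
    max_iter: int = 10
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.method not in ("als", "polynomial"):
            raise ValueError(f"unknown baseline method {self.method!r}")
        if self.als_lambda <= 0 or not (0 < self.als_p < 0.5):
            raise ValueError("require als_lambda > 0 and 0 < als_p < 0.5")
        if self.poly_degree < 0 or self.max_iter < 1 or self.tol <= 0:
            raise ValueError("invalid polynomial/iteration settings")


def _require_same_axis(a: RamanSpectrum, b: RamanSpectrum) -> None:
    if a.wavenumber_cm1.shape != b.wavenumber_cm1.shape or not np.allclose(
        a.wavenumber_cm1, b.wavenumber_cm1
    ):
        raise ValueError("spectra have different wavenumber axes")


def subtract_reference(
    spectrum: RamanSpectrum, reference: RamanSpectrum
) -> RamanSpectrum:
    """Subtract an instrument reference spectrum, clipping at zero."""
    _require_same_axis(spectrum, reference)
    diff = spectrum.intensity - reference.intensity
    clipped = int((diff < 0).sum())
    meta = dict(spectrum.meta)
    meta["reference_subtracted"] = True
    meta["clipped_points"] = clipped
    return RamanSpectrum(spectrum.wavenumber_cm1, np.clip(diff, 0.0, None), meta)


def _als_baseline(
    y: np.ndarray, lam: float, p: float, max_iter: int, tol: float
) -> tuple[np.ndarray, bool]:
    n = y.size
    d = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    penalty = lam * (d.T @ d)
    w = np.ones(n)
    z = y.copy()
    converged = False
    for _ in range(max_iter):
        W = sparse.diags(w)
        z_new = spsolve((W + penalty).tocsc(), w * y)
        w_new = np.where(y > z_new, p, 1.0 - p)
        if np.array_equal(w_new, w) or np.max(np.abs(z_new - z)) < tol * max(
            1.0, np.max(np.abs(y))
        ):
            z = z_new
            converged = True
            break
        z, w = z_new, w_new
    return z, converged


def _poly_baseline(
    x: np.ndarray, y: np.ndarray, degree: int, max_iter: int, tol: float
) -> tuple[np.ndarray, bool]:
    """Iterative polynomial fitting: points above the fit are clamped down to
    it each round, so the fit relaxes under the peaks."""
    u = (x - x[0]) / max(x[-1] - x[0], 1e-12)
    yy = y.copy()
    fit = np.zeros_like(y)
    converged = False
    for _ in range(max_iter):
        coeffs = np.polynomial.polynomial.polyfit(u, yy, degree)
        new_fit = np.polynomial.polynomial.polyval(u, coeffs)
        if np.max(np.abs(new_fit - fit)) < tol * max(1.0, np.max(np.abs(y))):
            fit = new_fit
            converged = True
            break
        fit = new_fit
        yy = np.minimum(yy, fit)
    return fit, converged


def remove_fluorescence(
    spectrum: RamanSpectrum, config: BaselineConfig = BaselineConfig()
) -> tuple[RamanSpectrum, np.ndarray]:
    """Estimate and subtract the fluorescence baseline.

    Returns the corrected spectrum (clipped at zero; ``corrected + baseline``
    reconstructs the input up to that clipping) and the baseline estimate.
    Non-convergence is flagged in ``meta['baseline_converged']`` and the best
    iterate returned.
    """
    y = spectrum.intensity
    if config.method == "als":
        baseline, converged = _als_baseline(
            y, config.als_lambda, config.als_p, config.max_iter, config.tol
        )
    else:
        baseline, converged = _poly_baseline(
            spectrum.wavenumber_cm1, y, config.poly_degree, config.max_iter, config.tol
        )
    meta = dict(spectrum.meta)
    meta["baseline_method"] = config.method
    meta["baseline_converged"] = bool(converged)
    corrected = RamanSpectrum(
        spectrum.wavenumber_cm1, np.clip(y - baseline, 0.0, None), meta
    )
    return corrected, baseline


def average_replicates(spectra: list[RamanSpectrum]) -> RamanSpectrum:
    """Pointwise mean over a sample's sweep replicates."""
    if not spectra:
        raise ValueError("no spectra to average")
    first = spectra[0]
    sample_ids = {s.meta.get("sample_id") for s in spectra}
    if len(sample_ids) > 1:
        raise ValueError(f"mixed sample ids in replicate set: {sorted(map(str, sample_ids))}")
    for s in spectra[1:]:
        _require_same_axis(first, s)
    mean = np.mean([s.intensity for s in spectra], axis=0)
    meta = dict(first.meta)
    meta["n_replicates"] = len(spectra)
    meta.pop("replicate", None)
    return RamanSpectrum(first.wavenumber_cm1, mean, meta)


def crop_window(
    spectrum: RamanSpectrum, lo: float = 600.0, hi: float = 2100.0
) -> RamanSpectrum:
    """Keep grid points in the inclusive analysis window [lo, hi] cm⁻¹."""
    if lo >= hi:
        raise ValueError("require lo < hi")
    keep = (spectrum.wavenumber_cm1 >= lo) & (spectrum.wavenumber_cm1 <= hi)
    if not keep.any():
        raise ValueError(f"window [{lo}, {hi}] cm⁻¹ contains no grid points")
    meta = dict(spectrum.meta)
    meta["window_cm1"] = (float(lo), float(hi))
    return RamanSpectrum(
        spectrum.wavenumber_cm1[keep], spectrum.intensity[keep], meta
    )


def resample(spectrum: RamanSpectrum, grid: np.ndarray) -> RamanSpectrum:
    """Linear interpolation onto a common grid; the spectrum must cover it."""
    grid = np.asarray(grid, dtype=float)
    w = spectrum.wavenumber_cm1
    if grid[0] < w[0] - 1e-9 or grid[-1] > w[-1] + 1e-9:
        raise ValueError(
            f"sample {spectrum.meta.get('sample_id', '?')} covers "
            f"[{w[0]:.1f}, {w[-1]:.1f}] cm⁻¹ but the target grid needs "
            f"[{grid[0]:.1f}, {grid[-1]:.1f}]"
        )
    return RamanSpectrum(
        grid, np.interp(grid, w, spectrum.intensity), dict(spectrum.meta)
    )


def to_feature_matrix(
    samples: list[RamanSpectrum],
    grid: np.ndarray,
    normalize: str = "none",
) -> tuple[pd.DataFrame, list[str | None]]:
    """Stack processed spectra into an (n_samples × n_gridpoints) matrix.

    Columns are wavenumbers; rows keep the sample order.  ``normalize`` is
    ``none``, ``vector`` (unit Euclidean norm per row) or ``area`` (unit sum).
    Returns the matrix and the per-row class labels (``None`` when absent).
    """
    if normalize not in ("none", "vector", "area"):
        raise ValueError(f"unknown normalization {normalize!r}")
    grid = np.asarray(grid, dtype=float)
    rows = []
    labels: list[str | None] = []
    index = []
    for i, s in enumerate(samples):
        r = resample(s, grid).intensity
        if normalize == "vector":
            nrm = np.linalg.norm(r)
            r = r / nrm if nrm > 0 else r
        elif normalize == "area":
            tot = r.sum()
            r = r / tot if tot > 0 else r
        rows.append(r)
        labels.append(s.meta.get("class_label"))
        index.append(s.meta.get("sample_id", f"sample_{i:04d}"))
    matrix = pd.DataFrame(np.asarray(rows), columns=grid, index=index)
    return matrix, labels
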