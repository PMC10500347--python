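"""Synthetic Raman spectra.

A spectrum is a sum of Gaussian band peaks on top of a smooth polynomial
fluorescence baseline, multiplied by a detector roll-off factor (germanium
quantum efficiency drops sharply above ~1350 cm⁻¹ at 780 nm excitation),
plus Gaussian noise whose SD scales with a per-class ``variability_scale``
(normal cells show 2–5× the spectral variability of cancer cells).

The polynomial baseline is parameterised on the reduced coordinate
``u = (w - 350) / (2100 - 350)`` so coefficients are O(1) regardless of the
wavenumber range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..types import RamanSpectrum

__all__ = [
    "SyntheticSpectrumParams",
    "default_wavenumber_grid",
    "generate_raman_spectrum",
    "generate_spectrum_population",
]

WAVENUMBER_MIN = 350.0
WAVENUMBER_MAX = 2100.0
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: roll-off end value: transmission multiplier retained at the top of the range
ROLLOFF_FLOOR = 0.2


@dataclass(frozen=True)
class SyntheticSpectrumParams:
    """Generative description of one class's Raman spectrum."""

    peak_centers: tuple[float, ...]
    peak_heights: tuple[float, ...]
    peak_widths: tuple[float, ...]  # FWHM, cm⁻¹
    baseline_coeffs: tuple[float, ...] = ()  # polynomial in u = (w-350)/1750, ascending
    noise_sd: float = 0.0
    variability_scale: float = 1.0
    rolloff_start: float = 1350.0

    def __post_init__(self) -> None:
        n = len(self.peak_centers)
        if not (len(self.peak_heights) == len(self.peak_widths) == n):
            raise ValueError("peak centers/heights/widths must have equal length")
        if any(w <= 0 for w in self.peak_widths):
            raise ValueError("peak widths must be > 0")
        for c in self.peak_centers:
            if not (WAVENUMBER_MIN <= c <= WAVENUMBER_MAX):
                raise ValueError(f"peak center {c} outside [350, 2100] cm⁻¹")
        if self.variability_scale < 0:
            raise ValueError("variability_scale must be >= 0")


def default_wavenumber_grid(step: float = 3.0) -> np.ndarray:
    """Uniform acquisition grid over the instrument range, 3 cm⁻¹ by default
    (comfortably below the 6 cm⁻¹ spectral resolution).  The grid starts at
    351 cm⁻¹ so that the 600 and 2100 cm⁻¹ analysis-window edges fall on
    grid points."""
    return np.arange(WAVENUMBER_MIN + 1.0, WAVENUMBER_MAX + 1e-9, step)


def _check_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or not np.all(np.diff(grid) > 0):
        raise ValueError("wavenumber grid must be 1D and strictly increasing")
    if grid[0] < WAVENUMBER_MIN - 1e-9 or grid[-1] > WAVENUMBER_MAX + 1e-9:
        raise ValueError("grid must lie within [350, 2100] cm⁻¹")
    return grid


def rolloff_factor(grid: np.ndarray, rolloff_start: float) -> np.ndarray:
    """Monotone multiplier: 1 below ``rolloff_start``, ramping linearly down to
    ``ROLLOFF_FLOOR`` at the top of the instrument range."""
    factor = np.ones_like(grid)
    span = WAVENUMBER_MAX - rolloff_start
    if span > 0:
        above = grid > rolloff_start
        frac = (grid[above] - rolloff_start) / span
        factor[above] = 1.0 - (1.0 - ROLLOFF_FLOOR) * frac
    return factor


def clean_spectrum(params: SyntheticSpectrumParams, grid: np.ndarray) -> np.ndarray:
    """Noise-free signal: (peaks + baseline) × roll-off."""
    grid = _check_grid(grid)
    signal = np.zeros_like(grid)
    for c, h, w in zip(params.peak_centers, params.peak_heights, params.peak_widths):
        sigma = w * _FWHM_TO_SIGMA
        signal += h * np.exp(-((grid - c) ** 2) / (2.0 * sigma**2))
    if params.baseline_coeffs:
        u = (grid - WAVENUMBER_MIN) / (WAVENUMBER_MAX - WAVENUMBER_MIN)
        signal += np.polynomial.polynomial.polyval(u, params.baseline_coeffs)
    return signal * rolloff_factor(grid, params.rolloff_start)


def generate_raman_spectrum(
    params: SyntheticSpectrumParams, grid: np.ndarray, seed: int
) -> RamanSpectrum:
    """One noisy spectrum; noise SD is ``noise_sd × variability_scale``;
    intensities are clipped at zero. Deterministic per seed."""
    grid = _check_grid(grid)
    rng = np.random.default_rng(seed)
    clean = clean_spectrum(params, grid)
    noise = rng.normal(0.0, params.noise_sd * params.variability_scale, size=grid.shape)
    return RamanSpectrum(
        grid,
        np.clip(clean + noise, 0.0, None),
        meta={"seed": int(seed), "rolloff_start": params.rolloff_start},
    )


def generate_spectrum_population(
    profiles: list,
    n_per_class: dict[str, int],
    replicates: int = 12,
    grid: np.ndarray | None = None,
    seed: int = 0,
    height_rel_sd: float = 0.04,
) -> list[tuple[str, list[RamanSpectrum]]]:
    """Draw a population of samples, each swept at ``replicates`` points.

    Replicates of one sample share sample-level peak heights (drawn with a
    relative SD of ``height_rel_sd × variability_scale`` around the class
    profile) and differ only in acquisition noise, emulating the 12-point
    sweep per sample.  Returns one ``(class_label, spectra)`` entry per
    sample; meta carries ``sample_id`` and ``replicate``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if grid is None:
        grid = default_wavenumber_grid()
    grid = _check_grid(grid)
    by_label = {p.class_label: p for p in profiles}
    for label in n_per_class:
        if label not in by_label:
            raise ValueError(f"unknown class label {label!r}")
    rng = np.random.default_rng(seed)
    out: list[tuple[str, list[RamanSpectrum]]] = []
    for label in sorted(n_per_class):
        sp = by_label[label].spectrum_profile
        for s in range(n_per_class[label]):
            mult = rng.normal(
                1.0, height_rel_sd * sp.variability_scale, size=len(sp.peak_heights)
            )
            heights = tuple(
                max(h * m, 0.0) for h, m in zip(sp.peak_heights, mult)
            )
            sample_params = SyntheticSpectrumParams(
                peak_centers=sp.peak_centers,
                peak_heights=heights,
                peak_widths=sp.peak_widths,
                baseline_coeffs=sp.baseline_coeffs,
                noise_sd=sp.noise_sd,
                variability_scale=sp.variability_scale,
                rolloff_start=sp.rolloff_start,
            )
            spectra = []
            sample_id = f"{label}_{s:03d}"
            for r in range(replicates):
                rep_seed = int(rng.integers(0, 2**31 - 1))
                spec = generate_raman_spectrum(sample_params, grid, rep_seed)
                spec.meta.update(
                    sample_id=sample_id, replicate=r, class_label=label
                )
                spectra.append(spec)
            out.append((label, spectra))
    return out
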