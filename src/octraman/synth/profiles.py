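"""Default class-conditional generator profiles for the five skin-cell types.

The study distinguishes two normal types (HaCaT keratinocytes, primary
melanocytes) and three cancer lines (SCC/A431, BCC, melanoma/A375).  No
quantitative effect sizes are tabulated for the morphometric features, so the
defaults below are free parameters chosen once to realize the qualitative
class structure at realistic skin-cell scales:

* cancer cells carry surface protrusions → rougher, less compact;
* keratinocyte-lineage cancers (SCC, BCC) are brighter than HaCaT;
* melanocytes are brighter than melanoma (melanin content);
* normal cells have larger internal-intensity SD (nucleus/cytoplasm contrast);
* BCC cells are larger than HaCaT and SCC.

Raman profiles share protein/lipid band positions near the reported ranges
(780, 935, 1000, 1290 cm⁻¹, plus 1450 and 1660 cm⁻¹), with partially
disjoint class-specific bands for the three cancer lines, a smooth cubic
fluorescence baseline, and a per-class variability scale putting normal-cell
spectral SD at 2–5× that of cancer cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .spectra import SyntheticSpectrumParams

__all__ = [
    "ClassProfile",
    "CLASS_LABELS",
    "NORMAL_CLASSES",
    "CANCER_CLASSES",
    "default_class_profiles",
]

CLASS_LABELS = ("HaCaT", "SCC", "BCC", "melanocyte", "melanoma")
NORMAL_CLASSES = ("HaCaT", "melanocyte")
CANCER_CLASSES = ("SCC", "BCC", "melanoma")


@dataclass(frozen=True)
class ClassProfile:
    """Per-class generator description: a (mean, SD) pair per cell-shape
    parameter plus the class's spectrum profile."""

    class_label: str
    param_distributions: dict[str, tuple[float, float]]
    spectrum_profile: SyntheticSpectrumParams

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        for key, (_, sd) in self.param_distributions.items():
            if sd < 0:
                raise ValueError(f"distribution SD for {key!r} must be >= 0")


# shared band structure (centers cm⁻¹, FWHM cm⁻¹); heights are per class
_BASE_CENTERS = (780.0, 935.0, 1000.0, 1290.0, 1450.0, 1660.0)
_BASE_WIDTHS = (12.0,) * 6

# smooth cubic fluorescence hump on u = (w-350)/1750
_BASELINE = (25.0, 55.0, -30.0, -25.0)

_NOISE_SD = 1.0


def _spectrum(
    base_heights: tuple[float, ...],
    extra: tuple[tuple[float, float], ...],
    variability: float,
) -> SyntheticSpectrumParams:
    centers = _BASE_CENTERS + tuple(c for c, _ in extra)
    heights = base_heights + tuple(h for _, h in extra)
    widths = _BASE_WIDTHS + (12.0,) * len(extra)
    return SyntheticSpectrumParams(
        peak_centers=centers,
        peak_heights=heights,
        peak_widths=widths,
        baseline_coeffs=_BASELINE,
        noise_sd=_NOISE_SD,
        variability_scale=variability,
        rolloff_start=1350.0,
    )


def default_class_profiles() -> list[ClassProfile]:
    """The shipped five-class generator configuration."""

    def shape(radius, count, amp, imean, isd):
        return {
            "radius_um": radius,
            "protrusion_count": count,
            "protrusion_amplitude_um": amp,
            "interior_mean": imean,
            "interior_sd": isd,
            "background_sd": (3.0, 0.0),
        }

    return [
        # --- normal: smoother, more compact, high internal contrast; broad
        # shape variability gives the classes overlapping V/C distributions,
        # as the study reports ---
        ClassProfile(
            "HaCaT",
            shape((6.4, 0.5), (3, 1.5), (0.40, 0.25), (80.0, 7.0), (22.0, 2.5)),
            _spectrum((60, 45, 70, 40, 50, 55), (), variability=4.0),
        ),
        ClassProfile(
            "melanocyte",
            shape((6.7, 0.5), (3, 1.5), (0.40, 0.25), (140.0, 8.0), (20.0, 2.5)),
            _spectrum((55, 40, 65, 45, 48, 52), (), variability=3.0),
        ),
        # --- cancer: protrusive, rough, low internal contrast ---
        ClassProfile(
            "SCC",
            shape((6.2, 0.5), (9, 2.5), (1.6, 0.45), (115.0, 7.0), (10.0, 1.5)),
            _spectrum(
                (75, 55, 85, 50, 45, 50),
                ((890.0, 55.0), (1340.0, 40.0)),
                variability=1.0,
            ),
        ),
        ClassProfile(
            "BCC",
            shape((7.8, 0.6), (9, 2.5), (1.6, 0.45), (112.0, 7.0), (10.0, 1.5)),
            _spectrum(
                (80, 60, 90, 42, 40, 45),
                ((850.0, 60.0), (1240.0, 50.0)),
                variability=1.0,
            ),
        ),
        ClassProfile(
            "melanoma",
            shape((6.5, 0.5), (10, 2.5), (1.7, 0.45), (105.0, 7.0), (11.0, 1.5)),
            _spectrum(
                (55, 45, 60, 55, 52, 58),
                ((970.0, 65.0), (1120.0, 55.0), (1550.0, 35.0)),
                variability=1.0,
            ),
        ),
    ]
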