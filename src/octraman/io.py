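"""File formats: multi-page TIFF stacks with JSON sidecars for volumes and
label maps, two-column CSV for spectra, CSV feature tables, JSON manifests.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .types import LabelMap, RamanSpectrum, Volume3D

__all__ = [
    "save_volume",
    "load_volume",
    "save_labels",
    "load_labels",
    "save_spectrum",
    "load_spectrum",
    "save_feature_table",
    "load_feature_table",
    "save_manifest",
    "load_manifest",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_volume(volume: Volume3D, path: str | Path) -> None:
    """Write one TIFF page per z-slice (float32) plus a JSON sidecar holding
    spacing and metadata."""
    path = Path(path)
    tifffile.imwrite(path, volume.data.astype(np.float32))
    side = {"spacing_um": list(volume.spacing), **_jsonable(volume.meta)}
    _sidecar(path).write_text(json.dumps(side, indent=1))


def load_volume(path: str | Path) -> Volume3D:
    path = Path(path)
    data = tifffile.imread(path).astype(np.float64)
    if data.ndim == 2:
        data = data[None]
    side = json.loads(_sidecar(path).read_text())
    spacing = tuple(side.pop("spacing_um"))
    return Volume3D(data, spacing, meta=side)


def save_labels(labels: LabelMap, path: str | Path) -> None:
    """Label stack as 16-bit TIFF plus JSON sidecar."""
    path = Path(path)
    if labels.labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 objects; 16-bit label TIFF overflows")
    tifffile.imwrite(path, labels.labels.astype(np.uint16))
    side = {"spacing_um": list(labels.spacing), **_jsonable(labels.meta)}
    _sidecar(path).write_text(json.dumps(side, indent=1))


def load_labels(path: str | Path) -> LabelMap:
    path = Path(path)
    data = tifffile.imread(path).astype(np.int32)
    if data.ndim == 2:
        data = data[None]
    side = json.loads(_sidecar(path).read_text())
    spacing = tuple(side.pop("spacing_um"))
    return LabelMap(data, spacing, meta=side)


def save_spectrum(spectrum: RamanSpectrum, path: str | Path) -> None:
    """Two-column CSV ``wavenumber_cm1,intensity``."""
    pd.DataFrame(
        {"wavenumber_cm1": spectrum.wavenumber_cm1, "intensity": spectrum.intensity}
    ).to_csv(path, index=False)


def load_spectrum(path: str | Path, meta: dict | None = None) -> RamanSpectrum:
    df = pd.read_csv(path)
    return RamanSpectrum(
        df["wavenumber_cm1"].to_numpy(float),
        df["intensity"].to_numpy(float),
        meta=dict(meta or {}),
    )


def save_feature_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


def load_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_manifest(entries: list[dict], path: str | Path) -> None:
    """Population manifest: one entry per sample
    ``{sample_id, class_label, files: [...]}``."""
    Path(path).write_text(json.dumps(entries, indent=1))


def load_manifest(path: str | Path) -> list[dict]:
    return json.loads(Path(path).read_text())


def _jsonable(meta: dict) -> dict:
    out = {}
    for k, v in meta.items():
        if isinstance(v, (np.integer,)):
            v = int(v)
        elif isinstance(v, (np.floating,)):
            v = float(v)
        elif isinstance(v, np.ndarray):
            v = v.tolist()
        elif isinstance(v, tuple):
            v = list(v)
        out[k] = v
    return out
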