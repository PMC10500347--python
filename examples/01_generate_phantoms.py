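"""Generate a synthetic OCT cell phantom and save it to disk.

Builds one protrusive (cancer-like) cell on the instrument grid
(0.45 µm lateral, 0.2 µm axial), adds a glass-slide reflection plane, and
writes the volume + ground truth as TIFF/JSON under ./scratch_example/.
"""

from pathlib import Path

from octraman import io
from octraman.synth import (
    SyntheticCellParams,
    add_reflection_planes,
    generate_cell_volume,
)

params = SyntheticCellParams(
    radius_um=6.0,
    protrusion_count=8,
    protrusion_amplitude_um=1.5,
    interior_mean=110.0,
    interior_sd=12.0,
    background_sd=3.0,
)
volume, truth = generate_cell_volume(
    params, spacing=(0.45, 0.45, 0.2), shape=(110, 50, 50), seed=42,
    class_label="SCC",
)
volume = add_reflection_planes(volume, [2], amplitude=400.0)

outdir = Path("scratch_example")
outdir.mkdir(exist_ok=True)
io.save_volume(volume, outdir / "cell.tif")
io.save_labels(truth.label_map, outdir / "cell_truth.tif")

cid, cls, vol_um3, centroid = truth.per_cell_truth[0]
print(f"volume shape (z,y,x): {volume.shape}, spacing {volume.spacing} um")
print(f"cell {cid} ({cls}): true volume {vol_um3:.1f} um^3, centroid {centroid}")
print("a reflection plane was added at z=2; the segmenter must crop it.")
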