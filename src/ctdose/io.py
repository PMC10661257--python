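"""NIfTI and JSON persistence for phantoms, sinograms and ROIs."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .metrics import ROI
from .phantom import PhantomSeries, VolumeTruth
from .projection import Sinogram


def save_series(series: PhantomSeries, path: str | Path) -> Path:
    """Write a phantom series as 4-D NIfTI (x, y, z, phase) with a JSON
    sidecar holding voxel spacing, phase fractions and the analytic truth."""
    path = Path(path)
    # NIfTI convention: x, y, z[, t]; our arrays are (z, y, x)
    data = np.stack([np.transpose(p, (2, 1, 0)) for p in series.phases], axis=-1)
    sx, sy, sz = series.voxel_spacing
    affine = np.diag([sx, sy, sz, 1.0])
    img = nib.Nifti1Image(data.astype(np.float32), affine)
    img.header.set_zooms((sx, sy, sz, 1.0))
    nib.save(img, str(path))
    sidecar = {
        "voxel_spacing_mm": list(series.voxel_spacing),
        "phase_fraction": list(series.phase_fraction),
        "fov_mm": series.fov_mm,
        "z_centers_mm": [float(z) for z in series.z_centers_mm],
        "truth": {
            "edv_ml": series.truth.edv_ml,
            "esv_ml": series.truth.esv_ml,
            "lvef_pct": series.truth.lvef_pct,
        },
    }
    sidecar_path = _sidecar_path(path)
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return path


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def load_truth(path: str | Path) -> VolumeTruth:
    sidecar = json.loads(_sidecar_path(Path(path)).read_text())
    t = sidecar["truth"]
    return VolumeTruth(t["edv_ml"], t["esv_ml"], t["lvef_pct"])


def load_volume(path: str | Path):
    """Load a NIfTI volume as ((phase list of) (z, y, x) arrays, spacing)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    zooms = img.header.get_zooms()
    spacing = tuple(float(z) for z in zooms[:3])
    if data.ndim == 4:
        phases = [np.transpose(data[..., t], (2, 1, 0)) for t in range(data.shape[-1])]
        return phases, spacing
    return np.transpose(data, (2, 1, 0)), spacing


def save_sinogram(sino: Sinogram, path: str | Path) -> Path:
    """Sinogram as .npz with a JSON metadata sidecar."""
    path = Path(path)
    np.savez_compressed(path, values=sino.values, angles_deg=sino.angles_deg)
    meta = {
        "detector_spacing_mm": sino.detector_spacing_mm,
        "n_pixels": sino.n_pixels,
        "meta": {k: v for k, v in sino.meta.items() if _jsonable(v)},
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path


def load_sinogram(path: str | Path) -> Sinogram:
    path = Path(path)
    arrays = np.load(path.with_suffix(".npz"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return Sinogram(
        values=arrays["values"],
        angles_deg=arrays["angles_deg"],
        detector_spacing_mm=meta["detector_spacing_mm"],
        n_pixels=meta["n_pixels"],
        meta=meta.get("meta", {}),
    )


def save_roi(roi: ROI, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(roi.to_dict(), indent=2))
    return path


def load_roi(path: str | Path) -> ROI:
    return ROI.from_dict(json.loads(Path(path).read_text()))


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
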