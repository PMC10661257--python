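"""Threshold-based left-ventricular volumetry.

Two measurement conventions are implemented, mirroring the two modes of
clinical cardiac-function software:

* **BV (blood volume)**: every voxel above an HU threshold inside the LV
  search region counts toward the volume; papillary muscles are excluded
  because they sit below the threshold.
* **ST (standard)**: the BV mask is closed slice-by-slice with a disk
  structuring element so interior papillary "holes" are absorbed, emulating
  contour-based delineation that includes the papillary muscles.

Per-phase volumes give the time-volume curve; end-diastole is the unique
maximum and end-systole the unique minimum, and LVEF = 100 (EDV - ESV)/EDV.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage
from skimage.morphology import disk
from skimage.transform import resize_local_mean


class SegmentationMode(str, Enum):
    BV = "bv"
    ST = "st"


@dataclass
class LVSegmentation:
    mask: np.ndarray
    threshold_hu: float
    mode: SegmentationMode


@dataclass
class TimeVolumeCurve:
    phase_fractions: list
    volumes_ml: list
    ed_index: int
    es_index: int


@dataclass(frozen=True)
class VolumeResult:
    edv_ml: float
    esv_ml: float
    lvef_pct: float
    mode: SegmentationMode


def _resolve_threshold(
    volume: np.ndarray,
    region: np.ndarray,
    threshold_policy: str,
    threshold_hu: float | None,
    blood_hu: float | None,
    myo_hu: float | None,
) -> float:
    if threshold_policy == "fixed":
        if threshold_hu is None:
            raise ValueError("fixed policy requires threshold_hu")
        return float(threshold_hu)
    if threshold_policy == "midpoint":
        if blood_hu is None or myo_hu is None:
            raise ValueError("midpoint policy requires blood_hu and myo_hu")
        return float(blood_hu + myo_hu) / 2.0
    if threshold_policy == "otsu":
        from skimage.filters import threshold_otsu

        return float(threshold_otsu(volume[region]))
    raise ValueError("threshold_policy must be 'fixed', 'midpoint' or 'otsu'")


def segment_lv(
    volume: np.ndarray,
    voxel_spacing: tuple,
    region: np.ndarray,
    mode: SegmentationMode | str = SegmentationMode.BV,
    threshold_policy: str = "midpoint",
    threshold_hu: float | None = None,
    blood_hu: float | None = None,
    myo_hu: float | None = None,
    closing_radius_mm: float = 10.0,
    presmooth_mm: float = 0.0,
) -> LVSegmentation:
    """Segment the LV blood pool of one 3-D HU volume.

    BV keeps the largest connected component above the threshold inside the
    search region (rejecting contrast that leaks past the threshold in other
    chambers); ST additionally closes each axial slice with a disk of
    ``closing_radius_mm`` so papillary inclusions are absorbed.  The final
    mask never leaves the search region.

    ``presmooth_mm`` applies an in-plane Gaussian of that sigma before
    thresholding, emulating the smoothing that precedes edge detection in
    automated contour software; callers typically scale it with the measured
    image noise.  Both modes share the smoothed volume, so the BV mask is
    always a subset of the ST mask.
    """
    mode = SegmentationMode(mode)
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise ValueError("LV search region is empty")
    if presmooth_mm > 0.02 * voxel_spacing[0]:
        s_px = presmooth_mm / voxel_spacing[0]
        volume = ndimage.gaussian_filter(volume, (0, s_px, s_px))
    thr = _resolve_threshold(
        volume, region, threshold_policy, threshold_hu, blood_hu, myo_hu
    )
    above = (volume >= thr) & region
    if not above.any():
        raise ValueError(
            f"empty segmentation at threshold {thr:.1f} HU; review the "
            "threshold policy or contrast level"
        )
    labels, n = ndimage.label(above)
    if n > 1:
        sizes = ndimage.sum_labels(above, labels, index=np.arange(1, n + 1))
        above = labels == (1 + int(np.argmax(sizes)))
    if mode is SegmentationMode.BV:
        return LVSegmentation(mask=above, threshold_hu=thr, mode=mode)

    radius_px = max(1, int(round(closing_radius_mm / voxel_spacing[0])))
    footprint = disk(radius_px)
    closed = np.zeros_like(above)
    pad = radius_px + 1
    for k in range(above.shape[0]):
        sl = np.pad(above[k], pad)
        sl = ndimage.binary_closing(sl, structure=footprint)
        closed[k] = sl[pad:-pad, pad:-pad]
    mask = (closed | above) & region
    return LVSegmentation(mask=mask, threshold_hu=thr, mode=mode)


def phase_volumes(
    phases,
    voxel_spacing: tuple,
    region: np.ndarray,
    mode: SegmentationMode | str = SegmentationMode.BV,
    threshold_policy: str = "midpoint",
    **kwargs,
) -> TimeVolumeCurve:
    """Segmented LV volume per phase and ED/ES identification.

    Raises if the maximum or minimum volume is not unique (a flat or
    ambiguous time-volume curve cannot define ED and ES).
    """
    phases = list(phases)
    if len(phases) < 2:
        raise ValueError("need at least 2 phases")
    fractions = kwargs.pop("phase_fractions", None)
    voxel_ml = float(np.prod(voxel_spacing)) / 1000.0
    volumes = []
    for vol in phases:
        seg = segment_lv(
            vol, voxel_spacing, region, mode, threshold_policy, **kwargs
        )
        volumes.append(float(seg.mask.sum()) * voxel_ml)
    vmax, vmin = max(volumes), min(volumes)
    if volumes.count(vmax) > 1 or volumes.count(vmin) > 1:
        raise ValueError(
            "time-volume curve has no unique maximum/minimum; ED and ES "
            "phases are not identifiable"
        )
    if fractions is None:
        fractions = [k / len(phases) for k in range(len(phases))]
    return TimeVolumeCurve(
        phase_fractions=fractions,
        volumes_ml=volumes,
        ed_index=int(np.argmax(volumes)),
        es_index=int(np.argmin(volumes)),
    )


def compute_lvef(edv_ml: float, esv_ml: float) -> float:
    """Ejection fraction 100 (EDV - ESV)/EDV, percent."""
    if not (edv_ml > esv_ml > 0):
        raise ValueError("need EDV > ESV > 0")
    return 100.0 * (edv_ml - esv_ml) / edv_ml


def measure_volumes(
    phases,
    voxel_spacing: tuple,
    region: np.ndarray,
    mode: SegmentationMode | str = SegmentationMode.BV,
    **kwargs,
) -> VolumeResult:
    """EDV, ESV and LVEF of a multi-phase volume series in one mode."""
    curve = phase_volumes(phases, voxel_spacing, region, mode, **kwargs)
    edv = curve.volumes_ml[curve.ed_index]
    esv = curve.volumes_ml[curve.es_index]
    return VolumeResult(
        edv_ml=edv,
        esv_ml=esv,
        lvef_pct=compute_lvef(edv, esv),
        mode=SegmentationMode(mode),
    )


def resample_output(
    volume: np.ndarray,
    in_slice_mm: float,
    in_pixel_mm: float = 1.0,
    out_thickness_mm: float = 1.0,
    out_increment_mm: float = 0.8,
    out_matrix: int = 256,
):
    """Sliding-average z-resampling plus in-plane local-mean resizing.

    Each output slice is the mean of input slices whose centers fall in an
    ``out_thickness_mm`` window stepped by ``out_increment_mm``; windows that
    would extend past the input extent are dropped with a warning.  In-plane
    the slices are resampled to ``out_matrix`` x ``out_matrix`` by
    area-weighted (local-mean) averaging, preserving the field of view.

    Returns ``(volume, (pixel_mm, increment_mm))``.
    """
    if in_slice_mm > out_thickness_mm:
        raise ValueError("input slice spacing must not exceed output thickness")
    n_in = volume.shape[0]
    extent = n_in * in_slice_mm
    in_centers = (np.arange(n_in) + 0.5) * in_slice_mm
    n_out = int(np.floor((extent - out_thickness_mm) / out_increment_mm)) + 1
    if n_out < 1:
        import warnings

        warnings.warn("output window exceeds input extent; no slices produced",
                      stacklevel=2)
        n_out = 0
    out_slices = []
    half = out_thickness_mm / 2.0
    for j in range(n_out):
        center = half + j * out_increment_mm
        sel = np.abs(in_centers - center) <= half + 1e-9
        out_slices.append(volume[sel].mean(axis=0))
    out = np.stack(out_slices) if out_slices else np.zeros((0,) + volume.shape[1:])
    if out_matrix != volume.shape[1] and out.shape[0] > 0:
        out = np.stack(
            [resize_local_mean(sl, (out_matrix, out_matrix)) for sl in out]
        )
    out_pixel = in_pixel_mm * volume.shape[1] / out_matrix
    return out, (out_pixel, out_increment_mm)
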