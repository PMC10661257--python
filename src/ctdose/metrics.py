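"""Image-quality metrics comparing reference and simulated images.

The optimization loop scores each candidate parameter set with three numbers
per reference series: the slope and R^2 of an ordinary least-squares fit of
simulated on real contrast-to-noise ratio across the dose ladder, and the
trapezoidal area under the masked-SSIM vs relative-dose curve.  The three are
min-max normalized across the candidate set and combined into a single
deviation norm

    deviation = sqrt((1-|slope|_n)^2 + (1-R^2_n)^2 + (1-AUC_n)^2),

which is zero for a candidate that attains the per-metric maxima.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from skimage.draw import polygon2mask
from skimage.metrics import structural_similarity

from ._utils import center_grids_mm
from .projection import ImageGrid

#: SSIM dynamic range: CT data offset to an unsigned 16-bit representation.
SSIM_DATA_RANGE = 65535.0
SSIM_OFFSET = 1024.0


@dataclass(frozen=True)
class ROI:
    """Circular or polygonal region of interest in image (mm) coordinates."""

    kind: str
    center: tuple | None = None
    radius_mm: float | None = None
    vertices_mm: tuple | None = None

    @classmethod
    def circle(cls, center, radius_mm: float) -> "ROI":
        if radius_mm <= 0:
            raise ValueError("radius must be positive")
        return cls(kind="circle", center=tuple(center), radius_mm=radius_mm)

    @classmethod
    def polygon(cls, vertices_mm) -> "ROI":
        vertices = tuple(tuple(v) for v in vertices_mm)
        if len(vertices) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        return cls(kind="polygon", vertices_mm=vertices)

    def mask(self, image: ImageGrid) -> np.ndarray:
        """Boolean mask of pixels whose centers fall inside the ROI."""
        n, s = image.matrix, image.spacing_mm
        if self.kind == "circle":
            xx, yy = center_grids_mm(n, s)
            cx, cy = self.center
            return (xx - cx) ** 2 + (yy - cy) ** 2 <= self.radius_mm**2
        # polygon: convert mm vertices to fractional pixel indices (row=y)
        verts = np.array(
            [
                ((y / s) + (n - 1) / 2.0, (x / s) + (n - 1) / 2.0)
                for x, y in self.vertices_mm
            ]
        )
        return polygon2mask((n, n), verts)

    def to_dict(self) -> dict:
        if self.kind == "circle":
            return {
                "kind": "circle",
                "center_mm": list(self.center),
                "radius_mm": self.radius_mm,
            }
        return {"kind": "polygon", "vertices_mm": [list(v) for v in self.vertices_mm]}

    @classmethod
    def from_dict(cls, d: dict) -> "ROI":
        if d["kind"] == "circle":
            return cls.circle(d["center_mm"], d["radius_mm"])
        return cls.polygon(d["vertices_mm"])


@dataclass(frozen=True)
class ROIStats:
    mean_hu: float
    sd_hu: float
    n_pixels: int


@dataclass(frozen=True)
class SSIMResult:
    mean_ssim: float
    mask_pixel_count: int


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r2: float


@dataclass
class ParameterMetrics:
    """Per-candidate metric bundle filled in two stages: raw metrics first,
    normalized values and deviation after the whole candidate set is known."""

    params: dict
    cnr_fit: RegressionFit
    auc_ssim: float
    slope_norm: float | None = None
    r2_norm: float | None = None
    auc_norm: float | None = None
    deviation: float | None = None
    extras: dict = field(default_factory=dict)


def roi_stats(image: ImageGrid, roi: ROI) -> ROIStats:
    """Mean and sample (n-1) SD of HU over pixels inside the ROI."""
    mask = roi.mask(image)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("ROI does not intersect the image")
    vals = image.pixels[mask]
    sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
    return ROIStats(mean_hu=float(vals.mean()), sd_hu=sd, n_pixels=n)


def cnr(x: ROIStats, y: ROIStats) -> float:
    """Contrast-to-noise ratio 2|HU(X)-HU(Y)| / (SD(X)+SD(Y))."""
    denom = x.sd_hu + y.sd_hu
    if denom <= 0:
        raise ValueError("CNR undefined: both ROI standard deviations are zero")
    return 2.0 * abs(x.mean_hu - y.mean_hu) / denom


def masked_ssim(
    a: ImageGrid,
    b: ImageGrid,
    mask: ROI,
    data_range: float = SSIM_DATA_RANGE,
) -> SSIMResult:
    """Mean SSIM over a masked region.

    The SSIM map is computed on the full images (11x11 Gaussian window,
    sigma 1.5, K1=0.01/K2=0.03) after offsetting HU into an unsigned 16-bit
    representation, then averaged over mask pixels whose window fits inside
    the image.
    """
    if a.pixels.shape != b.pixels.shape:
        raise ValueError("images must share one shape")
    au = np.clip(a.pixels + SSIM_OFFSET, 0, data_range)
    bu = np.clip(b.pixels + SSIM_OFFSET, 0, data_range)
    _, smap = structural_similarity(
        au,
        bu,
        gaussian_weights=True,
        sigma=1.5,
        use_sample_covariance=False,
        data_range=data_range,
        full=True,
    )
    pad = 5  # radius of the 11x11 window
    valid = np.zeros(smap.shape, dtype=bool)
    valid[pad:-pad, pad:-pad] = True
    m = mask.mask(a) & valid
    count = int(m.sum())
    if count == 0:
        raise ValueError("mask is empty (or entirely within the window border)")
    return SSIMResult(mean_ssim=float(smap[m].mean()), mask_pixel_count=count)


def auc_ssim(ssim_values, relative_doses) -> float:
    """Trapezoidal area under the SSIM vs relative-dose curve."""
    s = np.asarray(ssim_values, dtype=float)
    d = np.asarray(relative_doses, dtype=float)
    if s.shape != d.shape:
        raise ValueError("ssim_values and relative_doses must match in length")
    if s.size < 2:
        raise ValueError("need at least two dose levels")
    if np.any(np.diff(d) <= 0):
        raise ValueError("relative doses must be strictly increasing")
    return float(np.trapezoid(s, d))


def cnr_regression(real_cnr, simulated_cnr) -> RegressionFit:
    """OLS of simulated CNR on real CNR across the dose ladder."""
    x = np.asarray(real_cnr, dtype=float)
    y = np.asarray(simulated_cnr, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length inputs with at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("real CNR has zero variance; regression undefined")
    fit = stats.linregress(x, y)
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
    )


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        # a metric with no spread cannot discriminate; score everyone ideal
        return np.ones_like(values)
    return (values - lo) / (hi - lo)


def normalize_and_deviation(
    all_metrics: list[ParameterMetrics],
    slope_mode: str = "literal",
) -> list[ParameterMetrics]:
    """Min-max normalize |slope|, R^2 and AUC across candidates; attach the
    deviation norm to each.

    ``slope_mode='literal'`` normalizes |slope| directly, so the deviation
    rewards the largest slope magnitude in the candidate set.
    ``slope_mode='distance_to_ideal'`` instead normalizes 1 - |slope - 1|,
    rewarding slopes closest to one.
    """
    if len(all_metrics) < 2:
        out = []
        for m in all_metrics:
            out.append(
                replace(m, slope_norm=1.0, r2_norm=1.0, auc_norm=1.0, deviation=0.0)
            )
        return out
    if slope_mode == "literal":
        slope_score = np.array([abs(m.cnr_fit.slope) for m in all_metrics])
    elif slope_mode == "distance_to_ideal":
        slope_score = np.array(
            [1.0 - abs(m.cnr_fit.slope - 1.0) for m in all_metrics]
        )
    else:
        raise ValueError("slope_mode must be 'literal' or 'distance_to_ideal'")
    r2 = np.array([m.cnr_fit.r2 for m in all_metrics])
    auc = np.array([m.auc_ssim for m in all_metrics])
    sn, rn, an = _minmax(slope_score), _minmax(r2), _minmax(auc)
    out = []
    for m, s_, r_, a_ in zip(all_metrics, sn, rn, an):
        dev = float(np.sqrt((1 - s_) ** 2 + (1 - r_) ** 2 + (1 - a_) ** 2))
        out.append(
            replace(
                m,
                slope_norm=float(s_),
                r2_norm=float(r_),
                auc_norm=float(a_),
                deviation=dev,
            )
        )
    return out
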