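"""Digital chest/heart phantoms with analytically known LV volumes.

The phantom is a piecewise-constant stack of ellipses and ellipsoids: a
soft-tissue body ellipse with two lung fields and a spine disc, containing a
left ventricle modelled as a blood-filled ellipsoidal cavity inside a fixed
myocardial shell, with two papillary-muscle inserts at myocardial attenuation.
Cardiac motion is emulated by scaling the cavity semi-axes with a cosine over
the cycle, so every phase has an exact analytic cavity volume and the series
carries exact ground-truth EDV/ESV/LVEF (blood-volume convention: cavity minus
papillary muscles).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._utils import center_grids_mm
from .projection import ImageGrid


@dataclass(frozen=True)
class TissueModel:
    """HU assignment per tissue class.

    The LV blood pool must be at least 250 HU (a contrast-enhancement floor
    below which threshold segmentation of the cavity is unreliable) and
    strictly above myocardium.  Defaults put LV contrast in the range typical
    of clinical coronary CT angiography.
    """

    lv_blood_hu: float = 450.0
    myocardium_hu: float = 100.0
    papillary_hu: float | None = None
    lung_hu: float = -800.0
    soft_tissue_hu: float = 40.0
    bone_hu: float = 700.0
    air_hu: float = -1000.0

    def __post_init__(self):
        if self.papillary_hu is None:
            object.__setattr__(self, "papillary_hu", self.myocardium_hu)
        if self.lv_blood_hu < 250:
            raise ValueError(
                f"lv_blood_hu must be >= 250 HU (got {self.lv_blood_hu}); "
                "lower contrast does not support threshold segmentation"
            )
        if self.lv_blood_hu <= self.myocardium_hu:
            raise ValueError("lv_blood_hu must exceed myocardium_hu")
        if self.air_hu != -1000:
            raise ValueError("air_hu must be -1000 HU by definition")


@dataclass(frozen=True)
class PhantomGeometry:
    """All lengths in mm; (x, y) in-plane with origin at the image center,
    z along the slice stack.  ``lv_semiaxes`` are the end-diastolic cavity
    semi-axes; the myocardial outer shell is the cavity grown by
    ``shell_thickness_mm`` and does not move with the cardiac cycle."""

    body_center: tuple = (0.0, 0.0)
    body_semiaxes: tuple = (150.0, 100.0)
    lung_centers: tuple = ((-78.0, -5.0), (82.0, -5.0))
    lung_semiaxes: tuple = ((50.0, 62.0), (45.0, 62.0))
    lv_center: tuple = (30.0, 10.0, 0.0)
    lv_semiaxes: tuple = (32.0, 26.0, 42.0)
    shell_thickness_mm: float = 14.0
    papillary_offsets: tuple = ((11.0, 0.0, -8.0), (-11.0, 0.0, -8.0))
    papillary_semiaxes: tuple = ((9.0, 9.0, 17.0), (9.0, 9.0, 17.0))
    mitral_plane_z: float = 46.0
    spine_center: tuple = (0.0, -80.0)
    spine_radius: float = 13.0

    def __post_init__(self):
        a, b, c = self.lv_semiaxes
        for off, semi in zip(self.papillary_offsets, self.papillary_semiaxes):
            for o, s, ax in zip(off, semi, (a, b, c)):
                if abs(o) + s >= ax:
                    raise ValueError(
                        "papillary insert extends outside the LV cavity at "
                        "end-diastole"
                    )
        if self.mitral_plane_z < self.lv_center[2] + c:
            raise ValueError(
                "mitral_plane_z truncates the LV cavity; analytic volumes "
                "require the cap above the cavity apex"
            )

    # --- analytic volumes (mm^3) -------------------------------------
    def cavity_volume_mm3(self, scale: float = 1.0) -> float:
        a, b, c = self.lv_semiaxes
        return 4.0 / 3.0 * np.pi * a * b * c * scale**3

    def papillary_volume_mm3(self) -> float:
        return sum(
            4.0 / 3.0 * np.pi * sa * sb * sc
            for sa, sb, sc in self.papillary_semiaxes
        )

    def outer_shell_semiaxes(self) -> tuple:
        t = self.shell_thickness_mm
        a, b, c = self.lv_semiaxes
        return (a + t, b + t, c + t)


@dataclass(frozen=True)
class VolumeTruth:
    """Analytic end-diastolic/end-systolic volumes and ejection fraction."""

    edv_ml: float
    esv_ml: float
    lvef_pct: float

    def __post_init__(self):
        if not (0 < self.esv_ml < self.edv_ml):
            raise ValueError("need 0 < ESV < EDV")
        expected = 100.0 * (self.edv_ml - self.esv_ml) / self.edv_ml
        if abs(expected - self.lvef_pct) > 1e-9:
            raise ValueError("lvef_pct inconsistent with EDV/ESV")


@dataclass
class PhantomSeries:
    """Multi-phase HU volume stack with exact ground truth.

    ``phases`` are (n_slices, matrix, matrix) arrays indexed z, y, x;
    ``voxel_spacing`` is (x, y, z) in mm.
    """

    phases: list
    voxel_spacing: tuple
    phase_fraction: list
    truth: VolumeTruth
    geometry: PhantomGeometry
    tissue: TissueModel
    cavity_scales: list
    z_centers_mm: np.ndarray
    fov_mm: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.phases) < 2:
            raise ValueError("a dynamic series needs at least 2 phases")
        shape = self.phases[0].shape
        if any(p.shape != shape for p in self.phases):
            raise ValueError("all phases must share one shape")

    @property
    def matrix(self) -> int:
        return self.phases[0].shape[1]

    @property
    def n_slices(self) -> int:
        return self.phases[0].shape[0]


def _inside_ellipse(xx, yy, center, semiaxes):
    return ((xx - center[0]) / semiaxes[0]) ** 2 + (
        (yy - center[1]) / semiaxes[1]
    ) ** 2 <= 1.0


def _ellipsoid_section(xx, yy, center, semiaxes, z):
    """In-plane mask of an ellipsoid cut at height z (empty if outside)."""
    cx, cy, cz = center
    a, b, c = semiaxes
    dz = (z - cz) / c
    if abs(dz) >= 1.0:
        return np.zeros_like(xx, dtype=bool)
    shrink = np.sqrt(1.0 - dz**2)
    return _inside_ellipse(xx, yy, (cx, cy), (a * shrink, b * shrink))


def _check_fov(geometry: PhantomGeometry, fov_mm: float):
    half = fov_mm / 2.0
    checks = [
        ("body ellipse", geometry.body_center, geometry.body_semiaxes),
        *(
            (f"lung {i}", c, s)
            for i, (c, s) in enumerate(
                zip(geometry.lung_centers, geometry.lung_semiaxes)
            )
        ),
        (
            "spine disc",
            geometry.spine_center,
            (geometry.spine_radius, geometry.spine_radius),
        ),
    ]
    for name, center, semi in checks:
        if abs(center[0]) + semi[0] > half or abs(center[1]) + semi[1] > half:
            raise ValueError(f"{name} exceeds the {fov_mm} mm field of view")


def _paint_slice(
    geometry: PhantomGeometry,
    tissue: TissueModel,
    matrix: int,
    fov_mm: float,
    z_mm: float,
    cavity_scale: float,
) -> np.ndarray:
    spacing = fov_mm / matrix
    xx, yy = center_grids_mm(matrix, spacing)
    img = np.full((matrix, matrix), tissue.air_hu, dtype=float)

    img[_inside_ellipse(xx, yy, geometry.body_center, geometry.body_semiaxes)] = (
        tissue.soft_tissue_hu
    )
    for c, s in zip(geometry.lung_centers, geometry.lung_semiaxes):
        img[_inside_ellipse(xx, yy, c, s)] = tissue.lung_hu
    img[
        _inside_ellipse(
            xx, yy, geometry.spine_center,
            (geometry.spine_radius, geometry.spine_radius),
        )
    ] = tissue.bone_hu

    outer = _ellipsoid_section(
        xx, yy, geometry.lv_center, geometry.outer_shell_semiaxes(), z_mm
    )
    img[outer] = tissue.myocardium_hu

    if z_mm <= geometry.mitral_plane_z:
        a, b, c = geometry.lv_semiaxes
        cavity = _ellipsoid_section(
            xx,
            yy,
            geometry.lv_center,
            (a * cavity_scale, b * cavity_scale, c * cavity_scale),
            z_mm,
        )
        img[cavity] = tissue.lv_blood_hu
        lx, ly, lz = geometry.lv_center
        for off, semi in zip(
            geometry.papillary_offsets, geometry.papillary_semiaxes
        ):
            pap = _ellipsoid_section(
                xx, yy, (lx + off[0], ly + off[1], lz + off[2]), semi, z_mm
            )
            img[pap & cavity] = tissue.papillary_hu
    return img


def make_chest_slice(
    geometry: PhantomGeometry | None = None,
    tissue: TissueModel | None = None,
    matrix: int = 256,
    fov_mm: float = 350.0,
    z_mm: float | None = None,
    cavity_scale: float = 1.0,
) -> ImageGrid:
    """Render one axial chest slice as a piecewise-constant HU image.

    By default the slice passes through the LV center at end-diastole.
    """
    geometry = geometry or PhantomGeometry()
    tissue = tissue or TissueModel()
    if matrix < 64:
        raise ValueError("matrix must be >= 64")
    _check_fov(geometry, fov_mm)
    if z_mm is None:
        z_mm = geometry.lv_center[2]
    pixels = _paint_slice(geometry, tissue, matrix, fov_mm, z_mm, cavity_scale)
    return ImageGrid(pixels, fov_mm / matrix, meta={"z_mm": z_mm})


def make_dynamic_series(
    geometry: PhantomGeometry | None = None,
    tissue: TissueModel | None = None,
    n_phases: int = 6,
    target_lvef: float = 60.0,
    matrix: int = 192,
    fov_mm: float = 360.0,
    slice_thickness_mm: float = 6.0,
    z_margin_mm: float = 6.0,
) -> PhantomSeries:
    """Multi-phase phantom with cosine cavity motion hitting a target LVEF.

    The cavity volume follows V(phi) = ESV + (EDV - ESV)(1 + cos 2 pi phi)/2
    over cycle fraction phi, so phase 0 is end-diastole.  EDV/ESV/LVEF truth
    uses the blood-volume convention (analytic cavity minus papillary
    inserts); the scale of the end-systolic cavity is solved so the truth
    LVEF equals ``target_lvef`` exactly.
    """
    geometry = geometry or PhantomGeometry()
    tissue = tissue or TissueModel()
    if n_phases < 2:
        raise ValueError("n_phases must be >= 2")
    if not (0 < target_lvef < 100):
        raise ValueError("target_lvef must be in (0, 100)")
    _check_fov(geometry, fov_mm)

    edv_cav = geometry.cavity_volume_mm3(1.0)
    v_pap = geometry.papillary_volume_mm3()
    edv_bv = edv_cav - v_pap
    esv_bv = edv_bv * (1.0 - target_lvef / 100.0)
    esv_cav = esv_bv + v_pap
    s_min = (esv_cav / edv_cav) ** (1.0 / 3.0)

    a, b, c = geometry.lv_semiaxes
    for off, semi in zip(geometry.papillary_offsets, geometry.papillary_semiaxes):
        for o, s, ax in zip(off, semi, (a, b, c)):
            if abs(o) + s >= ax * s_min:
                raise ValueError(
                    "papillary insert leaves the cavity at end-systole; "
                    "reduce target_lvef or shrink the inserts"
                )

    fractions = [k / n_phases for k in range(n_phases)]
    scales = []
    for phi in fractions:
        v = esv_cav + (edv_cav - esv_cav) * (1.0 + np.cos(2 * np.pi * phi)) / 2.0
        scales.append((v / edv_cav) ** (1.0 / 3.0))

    a_out, b_out, c_out = geometry.outer_shell_semiaxes()
    z_lo = geometry.lv_center[2] - c_out - z_margin_mm
    z_hi = geometry.lv_center[2] + c_out + z_margin_mm
    n_slices = int(np.ceil((z_hi - z_lo) / slice_thickness_mm))
    z_centers = z_lo + (np.arange(n_slices) + 0.5) * slice_thickness_mm

    phases = []
    for s in scales:
        vol = np.stack(
            [
                _paint_slice(geometry, tissue, matrix, fov_mm, z, s)
                for z in z_centers
            ]
        )
        phases.append(vol)

    edv_ml = edv_bv / 1000.0
    esv_ml = esv_bv / 1000.0
    truth = VolumeTruth(
        edv_ml=edv_ml,
        esv_ml=esv_ml,
        lvef_pct=100.0 * (edv_ml - esv_ml) / edv_ml,
    )
    spacing = fov_mm / matrix
    return PhantomSeries(
        phases=phases,
        voxel_spacing=(spacing, spacing, slice_thickness_mm),
        phase_fraction=fractions,
        truth=truth,
        geometry=geometry,
        tissue=tissue,
        cavity_scales=scales,
        z_centers_mm=z_centers,
        fov_mm=fov_mm,
    )


def ground_truth_volumes(series: PhantomSeries) -> VolumeTruth:
    """The analytic (not voxel-counted) truth stored with the series."""
    return series.truth


def lv_region_mask(
    series: PhantomSeries, margin_mm: float = 6.0
) -> np.ndarray:
    """3-D boolean LV search region: the end-diastolic cavity ellipsoid grown
    by ``margin_mm``, capped at the mitral plane."""
    geometry = series.geometry
    spacing = series.voxel_spacing[0]
    xx, yy = center_grids_mm(series.matrix, spacing)
    a, b, c = (s + margin_mm for s in geometry.lv_semiaxes)
    mask = np.zeros((series.n_slices, series.matrix, series.matrix), dtype=bool)
    for k, z in enumerate(series.z_centers_mm):
        if z > geometry.mitral_plane_z:
            continue
        mask[k] = _ellipsoid_section(
            xx, yy, geometry.lv_center, (a, b, c), z
        )
    return mask


def default_rois(geometry: PhantomGeometry | None = None) -> dict:
    """Standard ROI set for metric and calibration runs.

    ``lv``: circle in the blood pool avoiding the papillary inserts;
    ``myo``: polygon along the lateral myocardial wall;
    ``heart_mask``: rectangle enclosing the heart, for masked SSIM.
    """
    from .metrics import ROI

    geometry = geometry or PhantomGeometry()
    lx, ly, _ = geometry.lv_center
    a, b, _ = geometry.lv_semiaxes
    t = geometry.shell_thickness_mm

    lv = ROI.circle((lx, ly + 14.0), 8.0)

    theta = np.linspace(-np.pi / 3, np.pi / 3, 13)
    outer_pts = [
        (lx + (a + t - 3.0) * np.cos(th), ly + (b + t - 3.0) * np.sin(th))
        for th in theta
    ]
    inner_pts = [
        (lx + (a + 3.0) * np.cos(th), ly + (b + 3.0) * np.sin(th))
        for th in reversed(theta)
    ]
    myo = ROI.polygon(outer_pts + inner_pts)

    a_out, b_out, _ = geometry.outer_shell_semiaxes()
    x0, x1 = lx - a_out - 10, lx + a_out + 10
    y0, y1 = ly - b_out - 10, ly + b_out + 10
    heart_mask = ROI.polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])
    return {"lv": lv, "myo": myo, "heart_mask": heart_mask}
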