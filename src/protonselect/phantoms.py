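"""Synthetic pelvic phantoms for prostate-radiotherapy plan comparison.

The phantoms are parametric: the prostate + seminal-vesicle clinical target
volume (CTV1) is an ellipsoid, the rectum a tube with a shell-like wall, the
bladder an anterior-superior ellipsoid, the femoral heads spheres, and the
pelvic lymph-node target (CTV2, dual-gradient cases only) an annular band.
Planning target volumes are obtained from the CTVs by anisotropic margin
expansion (1.0 cm superior/inferior/left/right/anterior and 0.5 cm posterior
for PTV1; 1.0/1.0/0.7/0.7/0.7/0.5 cm for PTV2), so the posterior PTV1 face
reaches into the anterior rectum wall exactly as in clinical prostate plans.

Coordinate convention (fixed throughout the package): arrays are indexed
``(z, y, x)`` with z running superior → inferior, y anterior → posterior and
x patient-right → patient-left; positions are voxel centres; ``spacing`` is
``(dz, dy, dx)`` in mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "CORE_ROIS",
    "PTV1_MARGINS",
    "PTV2_MARGINS",
    "MarginSpec",
    "CaseParams",
    "CohortSpec",
    "Phantom",
    "PhantomSizingError",
    "expand_ctv_to_ptv",
    "generate_phantom",
    "generate_cohort",
]

#: ROIs every phantom must carry.
CORE_ROIS = ("PTV1", "CTV1", "rectum", "rectum_wall", "bladder")


class PhantomSizingError(ValueError):
    """Raised when the requested grid cannot contain a structure."""


@dataclass(frozen=True)
class MarginSpec:
    """Direction-dependent CTV→PTV expansion margins in cm."""

    superior: float
    inferior: float
    left: float
    right: float
    anterior: float
    posterior: float

    def __post_init__(self) -> None:
        for name in ("superior", "inferior", "left", "right", "anterior", "posterior"):
            if getattr(self, name) < 0:
                raise ValueError(f"margin {name!r} must be >= 0, got {getattr(self, name)}")

    def mm(self, name: str) -> float:
        return 10.0 * getattr(self, name)


#: Clinical margins for the prostate + seminal-vesicle target.
PTV1_MARGINS = MarginSpec(superior=1.0, inferior=1.0, left=1.0, right=1.0,
                          anterior=1.0, posterior=0.5)
#: Clinical margins for the pelvic lymph-node target.
PTV2_MARGINS = MarginSpec(superior=1.0, inferior=1.0, left=0.7, right=0.7,
                          anterior=0.7, posterior=0.5)


@dataclass
class Phantom:
    """A labelled voxel patient: CT-like intensities plus binary ROI masks."""

    intensity: np.ndarray
    masks: dict[str, np.ndarray]
    spacing: tuple[float, float, float]
    patient_id: str = "case"
    anticoagulant_use: int = 0
    dual_gradient: bool = False
    ptv2_dose: float | None = None  # cGy, dual-gradient cases only

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape

    @property
    def voxel_volume_cc(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx / 1000.0

    def validate(self) -> None:
        shape = self.intensity.shape
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be > 0")
        if self.anticoagulant_use not in (0, 1):
            raise ValueError("anticoagulant_use must be 0 or 1")
        for roi in CORE_ROIS:
            if roi not in self.masks:
                raise ValueError(f"required ROI {roi!r} missing")
        for roi, mask in self.masks.items():
            if mask.shape != shape:
                raise ValueError(f"mask {roi!r} shape {mask.shape} != grid {shape}")
        if np.any(self.masks["rectum_wall"] & ~self.masks["rectum"]):
            raise ValueError("rectum_wall must be a subset of rectum")
        if np.any(self.masks["CTV1"] & ~self.masks["PTV1"]):
            raise ValueError("CTV1 must be a subset of PTV1")
        if "CTV2" in self.masks and "PTV2" in self.masks:
            if np.any(self.masks["CTV2"] & ~self.masks["PTV2"]):
                raise ValueError("CTV2 must be a subset of PTV2")


@dataclass(frozen=True)
class CaseParams:
    """Per-case generation parameters (derived from a :class:`CohortSpec`)."""

    shape: tuple[int, int, int] = (48, 64, 64)
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    dual_gradient: bool = False
    ptv2_dose: float = 4500.0
    anticoagulant_use: int = 0
    anatomy_variability: float = 1.0
    wall_thickness_mm: float = 3.0
    patient_id: str = "case_000"


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level generation parameters.

    ``fraction_dual_gradient`` is the proportion of cases whose target also
    covers the pelvic lymphatic drainage region (second dose level of 45 or
    50 Gy); ``anticoagulant_prevalence`` feeds the anticoagulant-use covariate
    of the logistic NTCP model.
    """

    n_cases: int = 20
    seed: int = 0
    fraction_dual_gradient: float = 0.5
    anticoagulant_prevalence: float = 0.2
    anatomy_variability: float = 1.0
    shape: tuple[int, int, int] = (48, 64, 64)
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    wall_thickness_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        for name in ("fraction_dual_gradient", "anticoagulant_prevalence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.anatomy_variability < 0:
            raise ValueError("anatomy_variability must be >= 0")


# ---------------------------------------------------------------------------
# margin expansion
# ---------------------------------------------------------------------------

def _dilate_axis(mask: np.ndarray, axis: int, n_neg: int, n_pos: int) -> np.ndarray:
    """Asymmetric binary dilation along one axis by whole-voxel shifts."""
    out = mask.copy()
    for k in range(1, n_neg + 1):  # shift content toward -axis == include voxels on the - side
        sl_src = [slice(None)] * mask.ndim
        sl_dst = [slice(None)] * mask.ndim
        sl_src[axis] = slice(k, None)
        sl_dst[axis] = slice(None, -k)
        out[tuple(sl_dst)] |= mask[tuple(sl_src)]
    for k in range(1, n_pos + 1):
        sl_src = [slice(None)] * mask.ndim
        sl_dst = [slice(None)] * mask.ndim
        sl_src[axis] = slice(None, -k)
        sl_dst[axis] = slice(k, None)
        out[tuple(sl_dst)] |= mask[tuple(sl_src)]
    return out


def expand_ctv_to_ptv(ctv_mask: np.ndarray, margins: MarginSpec,
                      spacing: tuple[float, float, float]) -> np.ndarray:
    """Expand a CTV mask into a PTV by direction-dependent margins.

    A voxel outside the CTV is included iff, for some CTV voxel, each signed
    per-axis centre-to-centre distance lies within the margin for that
    anatomical direction (superior/inferior along z, anterior/posterior along
    y, right/left along x). The test is separable, so the expansion is an
    asymmetric whole-voxel dilation with ``floor(margin / spacing)`` layers
    per direction.
    """
    ctv = np.asarray(ctv_mask).astype(bool)
    if not ctv.any():
        raise ValueError("CTV mask is empty; cannot expand an empty target")
    dz, dy, dx = spacing

    def layers(margin_mm: float, step: float) -> int:
        return int(math.floor(margin_mm / step + 1e-9))

    out = ctv.copy()
    # z: -z is superior, +z is inferior
    out = _dilate_axis(out, 0, layers(margins.mm("superior"), dz),
                       layers(margins.mm("inferior"), dz))
    # y: -y is anterior, +y is posterior
    out = _dilate_axis(out, 1, layers(margins.mm("anterior"), dy),
                       layers(margins.mm("posterior"), dy))
    # x: -x is patient-right, +x is patient-left
    out = _dilate_axis(out, 2, layers(margins.mm("right"), dx),
                       layers(margins.mm("left"), dx))
    return out


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def _grids_mm(shape, spacing):
    dz, dy, dx = spacing
    z = (np.arange(shape[0]) + 0.5) * dz
    y = (np.arange(shape[1]) + 0.5) * dy
    x = (np.arange(shape[2]) + 0.5) * dx
    return np.meshgrid(z, y, x, indexing="ij", sparse=True)


def _ellipsoid(Z, Y, X, center, semi) -> np.ndarray:
    cz, cy, cx = center
    az, ay, ax = semi
    return ((Z - cz) / az) ** 2 + ((Y - cy) / ay) ** 2 + ((X - cx) / ax) ** 2 <= 1.0


def _tube_z(Z, Y, X, center_yx, radius, z_lo, z_hi) -> np.ndarray:
    cy, cx = center_yx
    return ((Y - cy) ** 2 + (X - cx) ** 2 <= radius ** 2) & (Z >= z_lo) & (Z <= z_hi)


def _check_fits(mask: np.ndarray, roi: str) -> None:
    if not mask.any():
        raise PhantomSizingError(f"grid too small: ROI {roi!r} is empty at the requested size")
    edges = (mask[0].any() or mask[-1].any()
             or mask[:, 0].any() or mask[:, -1].any()
             or mask[:, :, 0].any() or mask[:, :, -1].any())
    if edges:
        raise PhantomSizingError(f"grid too small: ROI {roi!r} is clipped by the grid boundary")


# ---------------------------------------------------------------------------
# phantom generation
# ---------------------------------------------------------------------------

def generate_phantom(params: CaseParams, seed: int) -> Phantom:
    """Generate one pelvic phantom; bit-identical for identical inputs.

    The rectum tube is placed tangent to (or within a millimetre or two of)
    the posterior CTV1 surface, so the 0.5 cm posterior PTV1 margin carries
    the therapeutic dose gradient across the anterior rectum wall — the
    geometry the rectum-wall V6300cGy complication predictor probes.
    """
    shape = tuple(params.shape)
    if min(shape) < 32 and max(shape) < 32:
        raise PhantomSizingError(f"grid {shape} below the minimum supported size (32^3 region)")
    spacing = tuple(float(s) for s in params.spacing)
    rng = np.random.default_rng(seed)
    v = params.anatomy_variability
    dz, dy, dx = spacing
    ext_z, ext_y, ext_x = (n * s for n, s in zip(shape, spacing))

    Z, Y, X = _grids_mm(shape, spacing)
    masks: dict[str, np.ndarray] = {}

    # body: elliptic cylinder over the full cranio-caudal extent
    body_cy, body_cx = ext_y / 2, ext_x / 2
    body = ((Y - body_cy) / (0.44 * ext_y)) ** 2 + ((X - body_cx) / (0.47 * ext_x)) ** 2 <= 1.0
    body = np.broadcast_to(body, shape).copy()
    masks["body"] = body

    # prostate + seminal vesicles (CTV1): ellipsoid, centre mildly jittered
    # cranio-caudal position varies substantially between patients
    pc_z = 0.58 * ext_z + np.clip(rng.normal(0.0, 5.0 * v), -12.0, 12.0)
    pc_y = 0.54 * ext_y + rng.normal(0.0, 2.0 * v)
    pc_x = 0.50 * ext_x + rng.normal(0.0, 1.5 * v)
    semi_z = np.clip(16.0 + rng.normal(0.0, 2.0 * v), 10.0, 24.0)
    semi_y = np.clip(14.0 + rng.normal(0.0, 2.5 * v), 8.0, 22.0)
    semi_x = np.clip(17.0 + rng.normal(0.0, 2.0 * v), 10.0, 25.0)

    # rectum: tube along z just posterior of the CTV; the gap (possibly zero)
    # between CTV surface and rectum surface is a key variability driver
    r_rect = np.clip(11.0 + rng.normal(0.0, 2.0 * v), 7.0, 16.0)
    gap = np.clip(rng.normal(1.5, 2.0 * v), 0.0, 4.5)
    rect_cy = pc_y + semi_y + r_rect + gap
    rect_cx = pc_x + rng.normal(0.0, 1.5 * v)
    rect_zlo = pc_z - np.clip(30.0 + rng.normal(0.0, 4.0 * v), 20.0, 42.0)
    rect_zhi = min(pc_z + 40.0, ext_z - 1.5 * dz)
    rectum = _tube_z(Z, Y, X, (rect_cy, rect_cx), r_rect, rect_zlo, rect_zhi)

    ctv1 = _ellipsoid(Z, Y, X, (pc_z, pc_y, pc_x), (semi_z, semi_y, semi_x)) & ~rectum

    # rectum wall: shell of voxels within wall_thickness of the outer surface
    dist_in = ndimage.distance_transform_edt(rectum, sampling=spacing)
    rectum_wall = rectum & (dist_in <= params.wall_thickness_mm)

    # bladder: ellipsoid anterior-superior of the prostate
    bl_cz = pc_z - np.clip(28.0 + rng.normal(0.0, 3.0 * v), 20.0, 36.0)
    bl_cy = pc_y - semi_y - np.clip(14.0 + rng.normal(0.0, 2.0 * v), 8.0, 20.0)
    bladder = _ellipsoid(Z, Y, X, (bl_cz, bl_cy, pc_x),
                         (np.clip(18.0 + rng.normal(0.0, 2.0 * v), 12.0, 24.0),
                          np.clip(16.0 + rng.normal(0.0, 2.0 * v), 10.0, 22.0),
                          np.clip(18.0 + rng.normal(0.0, 2.0 * v), 12.0, 24.0)))
    bladder &= ~ctv1

    # femoral heads
    fem_r = 16.0
    fem_z = 0.60 * ext_z
    femur_r_mask = _ellipsoid(Z, Y, X, (fem_z, 0.52 * ext_y, 0.16 * ext_x),
                              (fem_r, fem_r, fem_r))
    femur_l_mask = _ellipsoid(Z, Y, X, (fem_z, 0.52 * ext_y, 0.84 * ext_x),
                              (fem_r, fem_r, fem_r))

    # bowel structures in the superior part of the grid
    colon = (((Z - 0.16 * ext_z) / 14.0) ** 2 + ((Y - 0.42 * ext_y) / 12.0) ** 2 <= 1.0) \
        & (np.abs(X - body_cx) <= 0.30 * ext_x)
    colon = np.broadcast_to(colon, shape) & body
    intestine = _ellipsoid(Z, Y, X, (0.14 * ext_z, 0.36 * ext_y, body_cx),
                           (12.0, 18.0, 0.22 * ext_x)) & ~colon

    masks.update({
        "CTV1": ctv1,
        "rectum": rectum,
        "rectum_wall": rectum_wall,
        "bladder": bladder,
        "femur_R": femur_r_mask,
        "femur_L": femur_l_mask,
        "colon": colon.copy(),
        "intestine": intestine,
    })

    masks["PTV1"] = expand_ctv_to_ptv(ctv1, PTV1_MARGINS, spacing)

    if params.dual_gradient:
        # pelvic lymph-node band: annulus around the vessels, posterior part removed
        rad = np.sqrt((Y - 0.46 * ext_y) ** 2 + (X - body_cx) ** 2)
        band = (rad >= 34.0) & (rad <= 48.0) & (Y <= 0.62 * ext_y)
        band = band & (Z >= 0.28 * ext_z) & (Z <= 0.52 * ext_z)
        ctv2 = band & body & ~rectum & ~bladder & ~ctv1
        if not ctv2.any():
            raise PhantomSizingError("grid too small: ROI 'CTV2' is empty at the requested size")
        masks["CTV2"] = ctv2
        masks["PTV2"] = expand_ctv_to_ptv(ctv2, PTV2_MARGINS, spacing)

    for roi in ("CTV1", "PTV1", "rectum", "rectum_wall", "bladder"):
        _check_fits(masks[roi], roi)
    if params.dual_gradient:
        _check_fits(masks["CTV2"], "CTV2")

    # CT-like intensities: soft tissue ~1000, bone ~1400, bowel gas low
    intensity = np.zeros(shape, dtype=np.float32)
    intensity[body] = 1000.0
    intensity[femur_r_mask | femur_l_mask] = 1400.0
    lumen = rectum & ~rectum_wall
    intensity[lumen] = 300.0
    intensity[bladder] = 1010.0
    intensity += rng.normal(0.0, 15.0, size=shape).astype(np.float32) * body
    intensity = np.clip(intensity, 0.0, None)

    phantom = Phantom(
        intensity=intensity,
        masks={k: m.astype(bool) for k, m in masks.items()},
        spacing=spacing,
        patient_id=params.patient_id,
        anticoagulant_use=int(params.anticoagulant_use),
        dual_gradient=bool(params.dual_gradient),
        ptv2_dose=float(params.ptv2_dose) if params.dual_gradient else None,
    )
    phantom.validate()
    return phantom


def case_params_from_spec(spec: CohortSpec) -> list[tuple[CaseParams, int]]:
    """Derive per-case parameters and seeds deterministically from a cohort spec."""
    rng = np.random.default_rng(spec.seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=spec.n_cases)
    dual = rng.random(spec.n_cases) < spec.fraction_dual_gradient
    anticoag = rng.random(spec.n_cases) < spec.anticoagulant_prevalence
    ptv2_choice = np.where(rng.random(spec.n_cases) < 0.5, 4500.0, 5000.0)
    out = []
    for i in range(spec.n_cases):
        params = CaseParams(
            shape=spec.shape,
            spacing=spec.spacing,
            dual_gradient=bool(dual[i]),
            ptv2_dose=float(ptv2_choice[i]),
            anticoagulant_use=int(anticoag[i]),
            anatomy_variability=spec.anatomy_variability,
            wall_thickness_mm=spec.wall_thickness_mm,
            patient_id=f"case_{i:03d}",
        )
        out.append((params, int(seeds[i])))
    return out


def generate_cohort(spec: CohortSpec) -> list[Phantom]:
    """Generate a reproducible cohort of phantoms from one cohort seed."""
    return [generate_phantom(params, seed) for params, seed in case_params_from_spec(spec)]
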