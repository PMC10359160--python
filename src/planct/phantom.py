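"""Paired synthetic thoracic CT phantoms with known ground-truth deformation.

Each case emulates the two acquisition states of a lung radiotherapy patient:

* a *diagnostic-like* volume (dCT): curved couch top, relaxed body contour,
  free-breathing diaphragm position;
* a *planning-like* volume (pCT): flat couch top, breath-hold anatomy with a
  larger lung volume (inferiorly displaced diaphragm dome) and a slightly
  expanded body contour.

The two states are linked by an analytic, C1-smooth pull-back displacement
``u`` (the planning volume samples the diagnostic volume at ``p + u(p)``),
built from two modes: a superior-directed sampling offset decaying smoothly
around the diaphragm dome (the anatomy appears shifted inferiorly, enlarging
the lungs), and a radial contraction of sampling positions about the body
axis (the body contour appears expanded). Both modes vanish near the spine
axis (rigid spine) and at the volume border, so the field is a small smooth
perturbation of the identity and is folding-free by construction.

Tissue intensities (HU): air -1000, lung -750, soft tissue 40, tumor 60,
spine bone 700, couch 200. Independent Gaussian noise is added to each state
after deformation, so the pair is never related by an exact intensity
identity. The couch differs categorically between the states and is excluded
from the deformation.

All geometry defaults are expressed relative to a reference 240 mm field of
view (96^3 voxels at 2.5 mm) and scale linearly with the grid extent, so
smaller desk-scale grids contain the same anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .volumes import (
    BinaryMask,
    DisplacementField,
    ScalarVolume,
    VolumeGrid,
    warp,
    warp_mask,
)

__all__ = [
    "Ellipsoid",
    "Sphere",
    "CouchModel",
    "PhantomSpec",
    "PhantomCase",
    "PhantomJitter",
    "default_grid",
    "make_phantom",
    "make_dataset",
]

HU_AIR = -1000.0
HU_LUNG = -750.0
HU_SOFT = 40.0
HU_TUMOR = 60.0
HU_BONE = 700.0
HU_COUCH = 200.0

_REF_EXTENT = 237.5  # mm, extent of the reference 96-voxel axis at 2.5 mm


@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]  # mm
    radii: tuple[float, float, float]  # mm

    def contains(self, x, y, z):
        return (
            ((x - self.center[0]) / self.radii[0]) ** 2
            + ((y - self.center[1]) / self.radii[1]) ** 2
            + ((z - self.center[2]) / self.radii[2]) ** 2
        ) <= 1.0


@dataclass(frozen=True)
class Sphere:
    center: tuple[float, float, float]  # mm
    radius: float  # mm

    @property
    def volume_cc(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius**3 / 1000.0

    def contains(self, x, y, z):
        return (
            (x - self.center[0]) ** 2
            + (y - self.center[1]) ** 2
            + (z - self.center[2]) ** 2
        ) <= self.radius**2


@dataclass(frozen=True)
class CouchModel:
    """Geometry of the couch band below the body (axial profile, all z)."""

    style: str  # "curved" | "flat"
    y_top: float  # mm, top surface at the couch midline
    thickness: float  # mm
    half_width: float  # mm, lateral half extent about the body axis
    sag_radius: float = 400.0  # mm, arc radius of the curved top
    hu: float = HU_COUCH

    def mask(self, grid: VolumeGrid) -> BinaryMask:
        x, y, _ = grid.coordinates()
        cx = grid.origin[0] + grid.extent_mm[0] / 2.0
        dx = x - cx
        if self.style == "curved":
            top = self.y_top + dx**2 / (2.0 * self.sag_radius)
        elif self.style == "flat":
            top = np.full_like(x, self.y_top)
        else:
            raise ValueError(f"unknown couch style {self.style!r}")
        inside = (np.abs(dx) <= self.half_width) & (y <= top) & (
            y >= top - self.thickness
        )
        return BinaryMask(grid, inside)


def default_grid(n: int = 96, spacing: float = 2.5) -> VolumeGrid:
    return VolumeGrid((n, n, n), (spacing, spacing, spacing))


@dataclass
class PhantomSpec:
    """Parameters of one synthetic patient.

    Geometry fields left as ``None`` are filled with defaults scaled to the
    grid extent (reference values in mm at a 240 mm field of view: body
    semi-axes 95 x 75, lung ellipsoids of radii 35 x 48 x 74 centered
    laterally at +/-45, tumor radius 9 in the right lung, diaphragm dome apex
    8.75 inferior of center, dome displacement 15, body contour change 3%).
    """

    grid: VolumeGrid = field(default_factory=default_grid)
    body_radii: tuple[float, float] | None = None
    lungs: tuple[Ellipsoid, Ellipsoid] | None = None
    tumor: Sphere | None = None
    diaphragm_z_dx: float | None = None
    diaphragm_shift: float | None = None
    body_scale: float = 0.03
    couch_style: str = "curved"
    noise_sd: float = 20.0
    seed: int = 0

    def __post_init__(self):
        L = min(self.grid.extent_mm[:2])
        Lz = self.grid.extent_mm[2]
        s = L / _REF_EXTENT
        c = self.center
        if self.body_radii is None:
            self.body_radii = (0.40 * L, 0.316 * L)
        if self.lungs is None:
            rad = (0.13 * L, 0.19 * L, 0.311 * Lz)
            self.lungs = tuple(
                Ellipsoid((c[0] + side * 0.18 * L, c[1] + 0.034 * L,
                           c[2] + 0.047 * Lz), rad)
                for side in (-1.0, +1.0)
            )
        if self.tumor is None:
            self.tumor = Sphere(
                (c[0] + 0.18 * L, c[1] + 0.034 * L, c[2] + 0.173 * Lz),
                9.04 * s,
            )
        if self.diaphragm_z_dx is None:
            self.diaphragm_z_dx = c[2] - 0.037 * Lz
        if self.diaphragm_shift is None:
            self.diaphragm_shift = 15.0 * s
        if self.diaphragm_shift < 0:
            raise ValueError("diaphragm_shift must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.couch_style not in ("curved", "flat"):
            raise ValueError(f"unknown couch style {self.couch_style!r}")

    @property
    def center(self) -> tuple[float, float, float]:
        return tuple(
            o + e / 2.0 for o, e in zip(self.grid.origin, self.grid.extent_mm)
        )

    @property
    def scale(self) -> float:
        """Linear size of this phantom relative to the reference extent."""
        return min(self.grid.extent_mm[:2]) / _REF_EXTENT

    def couch(self, style: str | None = None) -> CouchModel:
        L = min(self.grid.extent_mm[:2])
        return CouchModel(
            style=style or self.couch_style,
            y_top=self.grid.origin[1] + 0.084 * L,
            thickness=0.034 * L,
            half_width=0.33 * L,
            sag_radius=1.7 * L,
        )

    @property
    def spine(self) -> tuple[tuple[float, float], float]:
        """(axial center, radius) of the bony spine cylinder (mm)."""
        c = self.center
        L = min(self.grid.extent_mm[:2])
        return (c[0], c[1] - 0.21 * L), 0.05 * L


@dataclass
class PhantomCase:
    """A generated pair with its analytic ground truth.

    ``true_dvf`` maps planning-state sampling positions into the
    diagnostic-state source (pull-back): ``warp(dct_clean, true_dvf)`` equals
    ``pct_clean`` up to interpolation. The ``*_clean`` volumes are the
    noise-free, couch-free intermediates kept for testing and calibration.
    """

    spec: PhantomSpec
    dct: ScalarVolume
    pct: ScalarVolume
    true_dvf: DisplacementField
    masks_dct: dict[str, BinaryMask]
    masks_pct: dict[str, BinaryMask]
    dct_clean: ScalarVolume
    pct_clean: ScalarVolume
    couch_mask_dct: BinaryMask
    couch_mask_pct: BinaryMask


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _border_window(grid: VolumeGrid, margin: float) -> np.ndarray:
    """C1 window: 1 in the interior, 0 at the volume border (per-axis ramps)."""
    w = 1.0
    x, y, z = grid.coordinates()
    for a, coord in enumerate((x, y, z)):
        lo = grid.origin[a]
        hi = lo + grid.extent_mm[a]
        w = w * _smoothstep((coord - lo) / margin) * _smoothstep(
            (hi - coord) / margin
        )
    return w


def _true_displacement(spec: PhantomSpec) -> DisplacementField:
    grid = spec.grid
    if spec.diaphragm_shift == 0 and spec.body_scale == 0:
        return DisplacementField.zeros(grid)
    x, y, z = grid.coordinates()
    c = spec.center
    L = min(grid.extent_mm[:2])

    (sx, sy), s_rad = spec.spine
    d_spine2 = (x - sx) ** 2 + (y - sy) ** 2
    rho = 0.084 * L  # spine rigidity length scale
    spine_factor = 1.0 - np.exp(-d_spine2 / (2.0 * rho**2))
    window = _border_window(grid, 0.0625 * L) * spine_factor

    # diaphragm mode: superior-directed pull-back offset around the dome
    sig_z = 0.147 * L
    sig_lat = 0.295 * L
    r_ax2 = (x - c[0]) ** 2 + (y - c[1]) ** 2
    dome = np.exp(-((z - spec.diaphragm_z_dx) ** 2) / (2.0 * sig_z**2))
    dome = dome * np.exp(-r_ax2 / (2.0 * sig_lat**2))
    uz = spec.diaphragm_shift * dome

    # body contour mode: radial contraction of sampling positions about the
    # body axis makes the planning-state contour appear expanded by ~body_scale
    shrink = -spec.body_scale / (1.0 + spec.body_scale)
    ux = shrink * (x - c[0])
    uy = shrink * (y - c[1])

    u = np.stack([ux * window, uy * window, uz * window], axis=-1)
    return DisplacementField(grid, u)


def _analytic_masks(spec: PhantomSpec) -> dict[str, BinaryMask]:
    grid = spec.grid
    x, y, z = grid.coordinates()
    c = spec.center
    a, b = spec.body_radii
    body = ((x - c[0]) / a) ** 2 + ((y - c[1]) / b) ** 2 <= 1.0

    r_ax2 = (x - c[0]) ** 2 + (y - c[1]) ** 2
    L = min(grid.extent_mm[:2])
    # dome surface: apex on the body axis, falling off quadratically
    dome_z = spec.diaphragm_z_dx - r_ax2 / (2.0 * (0.42 * L))
    lung = np.zeros_like(body)
    for ell in spec.lungs:
        lung |= ell.contains(x, y, z)
    lung &= z > dome_z
    lung &= body
    gtv = spec.tumor.contains(x, y, z)
    return {
        "body": BinaryMask(grid, body),
        "lungs": BinaryMask(grid, lung),
        "gtv": BinaryMask(grid, gtv),
    }


def _render_clean(spec: PhantomSpec, masks: dict[str, BinaryMask]) -> ScalarVolume:
    grid = spec.grid
    x, y, _ = grid.coordinates()
    vals = np.full(grid.shape, HU_AIR)
    vals[masks["body"].values] = HU_SOFT
    vals[masks["lungs"].values] = HU_LUNG
    vals[masks["gtv"].values] = HU_TUMOR
    (sx, sy), s_rad = spec.spine
    spine = (x - sx) ** 2 + (y - sy) ** 2 <= s_rad**2
    vals[spine & masks["body"].values] = HU_BONE
    vals = gaussian_filter(vals, sigma=0.7)  # soften tissue interfaces
    return ScalarVolume(grid, vals)


def make_phantom(spec: PhantomSpec) -> PhantomCase:
    """Generate one paired case; identical spec (incl. seed) is bit-identical."""
    grid = spec.grid
    masks_dct = _analytic_masks(spec)
    if not masks_dct["body"].values.any() or not masks_dct["lungs"].values.any() \
            or not masks_dct["gtv"].values.any():
        raise ValueError("degenerate phantom geometry: an empty structure mask")
    if (masks_dct["lungs"].values & ~masks_dct["body"].values).any():
        raise ValueError("phantom geometry invalid: lungs extend outside body")
    if (masks_dct["gtv"].values & ~masks_dct["body"].values).any():
        raise ValueError("phantom geometry invalid: tumor extends outside body")

    dct_clean = _render_clean(spec, masks_dct)
    true_dvf = _true_displacement(spec)
    pct_clean = warp(dct_clean, true_dvf, interpolation="linear")
    masks_pct = {k: warp_mask(m, true_dvf) for k, m in masks_dct.items()}

    couch_d = spec.couch(spec.couch_style).mask(grid)
    couch_p = spec.couch("flat").mask(grid)
    for couch, body in ((couch_d, masks_dct["body"]), (couch_p, masks_pct["body"])):
        if (couch.values & body.values).any():
            raise ValueError("phantom geometry invalid: couch overlaps body")

    rng = np.random.default_rng(spec.seed)
    dct_vals = dct_clean.values.copy()
    dct_vals[couch_d.values] = HU_COUCH
    pct_vals = pct_clean.values.copy()
    pct_vals[couch_p.values] = HU_COUCH
    if spec.noise_sd > 0:
        dct_vals = dct_vals + rng.normal(0.0, spec.noise_sd, grid.shape)
        pct_vals = pct_vals + rng.normal(0.0, spec.noise_sd, grid.shape)

    return PhantomCase(
        spec=spec,
        dct=ScalarVolume(grid, dct_vals),
        pct=ScalarVolume(grid, pct_vals),
        true_dvf=true_dvf,
        masks_dct=masks_dct,
        masks_pct=masks_pct,
        dct_clean=dct_clean,
        pct_clean=pct_clean,
        couch_mask_dct=couch_d,
        couch_mask_pct=couch_p,
    )


@dataclass(frozen=True)
class PhantomJitter:
    """Uniform per-case parameter ranges for dataset generation.

    Geometric ranges are relative factors; the tumor radius range is in mm at
    the reference extent (scaled with the grid) and is calibrated so the
    voxelized GTV volumes of a default draw have a median near 3.1 cc.
    """

    body_radii_factor: tuple[float, float] = (0.92, 1.08)
    lung_radii_factor: tuple[float, float] = (0.90, 1.10)
    tumor_radius_mm: tuple[float, float] = (7.6, 10.6)
    diaphragm_shift_mm: tuple[float, float] = (10.0, 20.0)
    body_scale: tuple[float, float] = (0.02, 0.04)
    target_gtv_cc: tuple[float, float] = (2.0, 4.5)  # documentation of intent

    def __post_init__(self):
        for name in ("body_radii_factor", "lung_radii_factor", "tumor_radius_mm",
                     "diaphragm_shift_mm", "body_scale"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValueError(f"empty jitter range for {name}: ({lo}, {hi})")

    def draw(self, base: PhantomSpec, rng: np.random.Generator) -> PhantomSpec:
        s = base.scale
        bf = rng.uniform(*self.body_radii_factor)
        lf = rng.uniform(*self.lung_radii_factor)
        tr = rng.uniform(*self.tumor_radius_mm) * s
        shift = rng.uniform(*self.diaphragm_shift_mm) * s
        bscale = rng.uniform(*self.body_scale)
        lungs = tuple(
            Ellipsoid(e.center, tuple(r * lf for r in e.radii)) for e in base.lungs
        )
        return replace(
            base,
            body_radii=tuple(r * bf for r in base.body_radii),
            lungs=lungs,
            tumor=Sphere(base.tumor.center, tr),
            diaphragm_shift=shift,
            body_scale=bscale,
        )


def make_dataset(
    n_cases: int,
    base_seed: int = 0,
    jitter: PhantomJitter | None = None,
    grid: VolumeGrid | None = None,
) -> list[PhantomCase]:
    """Generate ``n_cases`` jittered cases with per-case seeds base_seed + i."""
    if n_cases < 1:
        raise ValueError(f"n_cases must be >= 1, got {n_cases}")
    jitter = jitter or PhantomJitter()
    grid = grid or default_grid()
    cases = []
    for i in range(n_cases):
        seed = base_seed + i
        base = PhantomSpec(grid=grid, seed=seed)
        spec = jitter.draw(base, np.random.default_rng(seed))
        cases.append(make_phantom(spec))
    return cases
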