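"""Synthetic multi-center labyrinth-phantom cohorts.

The clinical study this package re-implements used four-center T2-weighted MR
volumes of manually segmented inner-ear labyrinths; those data are not
publicly deposited.  This module generates a seeded stand-in cohort with the
statistical structure the downstream analysis assumes:

* a labyrinth-like region of interest: a vestibule ellipsoid plus three
  mutually orthogonal semicircular-canal torus arcs;
* a two-class contrast: "patients" carry a focal hypointense sub-region
  (emulating a saccule-scale signal drop), an optional texture
  correlation-length shift and an optional sub-voxel shape dilation;
* per-center acquisition differences: affine intensity transforms and
  anisotropic voxel spacing;
* additive Gaussian (optionally Rician) noise with a tunable spatial
  correlation length.

The three canal arcs are offset from their common center so that the four
solids are pairwise disjoint; the analytic ROI volume is then simply the
ellipsoid volume plus three partial-torus volumes, which keeps the geometry
checkable in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .volume import ImageVolume, SegMask

__all__ = [
    "PhantomParams",
    "ClassEffect",
    "CenterEffect",
    "CohortSpec",
    "generate_phantom",
    "generate_cohort",
    "iter_cohort",
    "table1_cohort_spec",
]

PATIENT = "patient"
CONTROL = "control"

#: angular margin (radians) trimmed from each end of the half-circle canal
#: arcs; keeps the three tubes pairwise disjoint so analytic volumes add up.
_ARC_MARGIN = math.radians(15.0)
#: offset (mm) of each canal ring plane from the vestibule center.
_CANAL_PLANE_OFFSET = 1.2


@dataclass
class PhantomParams:
    """Geometry and intensity parameters of one labyrinth phantom.

    All lengths in mm, intensities in arbitrary MR units.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    vestibule_radii: tuple[float, float, float] = (3.2, 2.4, 2.0)
    canal_radius: float = 5.0
    canal_tube_radius: float = 0.9
    roi_intensity_mean: float = 300.0
    background_mean: float = 100.0
    noise_sigma: float = 20.0
    noise_corr_mm: float = 0.4
    rician: bool = False

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.vestibule_radii):
            raise ValueError(f"vestibule_radii must be positive, got {self.vestibule_radii}")
        if self.canal_radius <= 0 or self.canal_tube_radius <= 0:
            raise ValueError("canal radii must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def validate_extent(self, spacing: tuple[float, float, float]) -> None:
        """Raise if the phantom would not fit inside the grid."""
        half_extent = [self.grid_shape[a] * spacing[a] / 2.0 for a in range(3)]
        reach = self.canal_radius + self.canal_tube_radius + _CANAL_PLANE_OFFSET
        for a, h in enumerate(half_extent):
            if self.vestibule_radii[a] >= h:
                raise ValueError(
                    f"vestibule radius {self.vestibule_radii[a]} mm exceeds grid "
                    f"half-extent {h:.2f} mm on axis {a}"
                )
            if reach >= h:
                raise ValueError(
                    f"canal radius {self.canal_radius} mm (+tube {self.canal_tube_radius} mm) "
                    f"exceeds grid half-extent {h:.2f} mm on axis {a}"
                )

    def analytic_roi_volume(self) -> float:
        """Closed-form ROI volume in mm^3 (disjoint ellipsoid + 3 arcs)."""
        a, b, c = self.vestibule_radii
        v_ell = 4.0 / 3.0 * math.pi * a * b * c
        arc_fraction = (math.pi - 2 * _ARC_MARGIN) / (2 * math.pi)
        v_arc = 2 * math.pi**2 * self.canal_radius * self.canal_tube_radius**2 * arc_fraction
        return v_ell + 3 * v_arc


@dataclass
class ClassEffect:
    """Patient-vs-control contrast injected into patient phantoms.

    ``focal_hypointensity_delta`` is expressed in units of the ROI noise SD
    (absolute intensity units when ``noise_sigma == 0``), so effect size is
    tied to noise for power experiments.  Setting every field to 0 makes the
    two classes identically distributed.
    """

    focal_hypointensity_delta: float = 3.0
    focal_fraction: float = 0.15
    texture_corr_length_shift: float = 0.2
    shape_dilation_mm: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.focal_fraction <= 1.0:
            raise ValueError(f"focal_fraction must be in [0,1], got {self.focal_fraction}")

    @classmethod
    def null(cls) -> "ClassEffect":
        """All-zero effect: classes are identically distributed."""
        return cls(0.0, 0.0, 0.0, 0.0)

    @property
    def is_null(self) -> bool:
        return (
            self.focal_hypointensity_delta == 0
            and self.texture_corr_length_shift == 0
            and self.shape_dilation_mm == 0
        )


@dataclass
class CenterEffect:
    """Per-center acquisition model: affine intensity transform + spacing."""

    name: str = "A"
    intensity_scale: float = 1.0
    intensity_offset: float = 0.0
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)

    def __post_init__(self) -> None:
        if self.intensity_scale <= 0:
            raise ValueError("intensity_scale must be > 0")


#: default four-center acquisition models (heterogeneous scales, offsets and
#: anisotropic spacings, emulating non-constant scan parameters).
DEFAULT_CENTERS = (
    CenterEffect("A", 1.00, 0.0, (0.5, 0.5, 0.5)),
    CenterEffect("B", 1.25, 40.0, (0.4, 0.4, 0.6)),
    CenterEffect("C", 0.80, -25.0, (0.6, 0.6, 0.6)),
    CenterEffect("D", 1.10, 15.0, (0.5, 0.5, 0.8)),
)


@dataclass
class CohortSpec:
    """Recipe for a seeded multi-center two-class cohort."""

    n_patients: dict[str, int]
    n_controls: dict[str, int]
    seed: int = 0
    phantom: PhantomParams = field(default_factory=PhantomParams)
    effect: ClassEffect = field(default_factory=ClassEffect)
    centers: tuple[CenterEffect, ...] = DEFAULT_CENTERS

    def __post_init__(self) -> None:
        names = {c.name for c in self.centers}
        for d in (self.n_patients, self.n_controls):
            for center, n in d.items():
                if center not in names:
                    raise ValueError(f"unknown center {center!r}")
                if n < 0:
                    raise ValueError("cohort counts must be >= 0")

    @property
    def total(self) -> int:
        return sum(self.n_patients.values()) + sum(self.n_controls.values())


def table1_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """The study-shaped default cohort: 120 patient ears vs 140 control ears
    over four centers (A 48/23, B 33/24, C 33/75, D 6/18), 260 ears total.
    """
    spec = CohortSpec(
        n_patients={"A": 48, "B": 33, "C": 33, "D": 6},
        n_controls={"A": 23, "B": 24, "C": 75, "D": 18},
        seed=seed,
    )
    return replace(spec, **overrides) if overrides else spec


def _grid_coords(shape, spacing):
    """Physical voxel-center coordinates relative to the grid center, mm."""
    axes = [
        (np.arange(shape[a]) - (shape[a] - 1) / 2.0) * spacing[a]
        for a in range(3)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _arc_mask(u, v, w, R, r, margin):
    """Torus-arc solid in the (u, v) plane at w-offset already applied.

    Keeps angular range [margin, pi - margin] of the ring (v-positive side).
    """
    rho = np.sqrt(u**2 + v**2)
    tube = (rho - R) ** 2 + w**2 <= r**2
    theta = np.arctan2(v, u)
    return tube & (theta >= margin) & (theta <= math.pi - margin)


def _voxelize_labyrinth(params: PhantomParams, spacing, dilation_mm: float = 0.0):
    """Binary voxelization (voxel-center rule) of the labyrinth solid.

    ``dilation_mm`` grows every radius analytically, giving sub-voxel-capable
    shape changes for the patient class.
    """
    x, y, z = _grid_coords(params.grid_shape, spacing)
    a, b, c = (r + dilation_mm for r in params.vestibule_radii)
    R = params.canal_radius
    r = params.canal_tube_radius + dilation_mm
    off = _CANAL_PLANE_OFFSET

    vestibule = (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0
    # lateral-like canal: ring in plane z=+off, y-positive arc
    c1 = _arc_mask(x, y, z - off, R, r, _ARC_MARGIN)
    # posterior-like canal: ring in plane y=-off, z-positive arc
    c2 = _arc_mask(x, z, y + off, R, r, _ARC_MARGIN)
    # superior-like canal: ring in plane x=+off, z-negative arc
    c3 = _arc_mask(-y, -z, x - off, R, r, _ARC_MARGIN)
    mask = vestibule | c1 | c2 | c3
    return mask, vestibule, (x, y, z)


def _focal_region(mask, coords, fraction):
    """Saccule-like sub-region: the ``fraction`` of ROI voxels closest (in a
    squashed ellipsoidal metric) to a point offset below the vestibule center.
    """
    if fraction <= 0:
        return np.zeros_like(mask)
    x, y, z = coords
    # anisotropic distance, centered slightly inferior to the vestibule center
    d = (x / 1.6) ** 2 + (y / 1.0) ** 2 + ((z + 0.8) / 0.9) ** 2
    d_roi = d[mask]
    k = max(1, int(round(fraction * d_roi.size)))
    thresh = np.partition(d_roi, k - 1)[k - 1]
    return mask & (d <= thresh)


def _correlated_noise(rng, shape, spacing, corr_mm):
    """Unit-SD Gaussian field with approximate correlation length corr_mm."""
    white = rng.standard_normal(shape)
    if corr_mm > 0:
        sig = [corr_mm / s for s in spacing]
        white = gaussian_filter(white, sigma=sig, mode="nearest")
        sd = white.std()
        if sd > 0:
            white = white / sd
    return white


def generate_phantom(
    params: PhantomParams,
    label: str,
    effect: ClassEffect,
    center: CenterEffect,
    seed: int,
) -> tuple[ImageVolume, SegMask]:
    """Generate one labyrinth phantom ear: image + mask.

    Deterministic given ``seed``.  The mask is the voxelization of the
    ellipsoid-plus-arcs solid; the image is ``background_mean`` outside the
    ROI and ``roi_intensity_mean`` inside, with the class effect (patients
    only), spatially correlated noise and the center's affine intensity
    transform applied.
    """
    if label not in (PATIENT, CONTROL):
        raise ValueError(f"label must be {PATIENT!r} or {CONTROL!r}, got {label!r}")
    spacing = center.spacing
    params.validate_extent(spacing)

    is_patient = label == PATIENT
    dilation = effect.shape_dilation_mm if is_patient else 0.0
    mask, _, coords = _voxelize_labyrinth(params, spacing, dilation)

    image = np.full(params.grid_shape, params.background_mean, dtype=np.float64)
    image[mask] = params.roi_intensity_mean

    if is_patient and effect.focal_hypointensity_delta != 0:
        sd_unit = params.noise_sigma if params.noise_sigma > 0 else 1.0
        focal = _focal_region(mask, coords, effect.focal_fraction)
        image[focal] -= effect.focal_hypointensity_delta * sd_unit

    rng = np.random.default_rng(seed)
    if params.noise_sigma > 0:
        corr = params.noise_corr_mm + (effect.texture_corr_length_shift if is_patient else 0.0)
        if params.rician:
            n1 = _correlated_noise(rng, params.grid_shape, spacing, corr)
            n2 = _correlated_noise(rng, params.grid_shape, spacing, corr)
            image = np.sqrt(
                (image + params.noise_sigma * n1) ** 2 + (params.noise_sigma * n2) ** 2
            )
        else:
            image = image + params.noise_sigma * _correlated_noise(
                rng, params.grid_shape, spacing, corr
            )

    image = center.intensity_scale * image + center.intensity_offset
    vol = ImageVolume(image.astype(np.float32), spacing)
    seg = SegMask(mask.astype(np.uint8), spacing)
    return vol, seg


def _ear_seed(master_seed: int, index: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def iter_cohort(spec: CohortSpec):
    """Yield ``(ear_id, label, center_name, ImageVolume, SegMask)`` for every
    ear in the cohort, in a fixed deterministic order.
    """
    centers = {c.name: c for c in spec.centers}
    idx = 0
    for center_name in sorted(set(spec.n_patients) | set(spec.n_controls)):
        center = centers[center_name]
        for label, counts in ((PATIENT, spec.n_patients), (CONTROL, spec.n_controls)):
            for k in range(counts.get(center_name, 0)):
                ear_id = f"{center_name}_{'md' if label == PATIENT else 'ctl'}_{k:03d}"
                vol, seg = generate_phantom(
                    spec.phantom, label, spec.effect, center, _ear_seed(spec.seed, idx)
                )
                yield ear_id, label, center_name, vol, seg
                idx += 1


def generate_cohort(spec: CohortSpec, out_dir) -> pd.DataFrame:
    """Write a cohort to disk: one NIfTI image + mask per ear and a cohort
    table CSV (``id,label,center,image_path,mask_path``).  Returns the table.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    seen = set()
    for ear_id, label, center_name, vol, seg in iter_cohort(spec):
        if ear_id in seen:
            raise ValueError(f"duplicate ear id {ear_id!r}")
        seen.add(ear_id)
        img_path = out / f"{ear_id}_img.nii.gz"
        msk_path = out / f"{ear_id}_mask.nii.gz"
        vol.save(img_path)
        seg.save(msk_path)
        rows.append(
            {
                "id": ear_id,
                "label": label,
                "center": center_name,
                "image_path": str(img_path),
                "mask_path": str(msk_path),
            }
        )
    table = pd.DataFrame(rows, columns=["id", "label", "center", "image_path", "mask_path"])
    table.to_csv(out / "cohort.csv", index=False)
    return table
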