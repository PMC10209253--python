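"""Synthetic co-registered CT/PET phantoms with known ground truth.

A phantom holds bone-like HU structures (cortical shell + marrow), a
soft-tissue body, physiologic high-uptake organs outside bone, and osseous
lesions of known volume and SUV plateau. The PET volume is produced by
back-converting the designed SUV map to activity concentration with the
same SUV factors the DICOM reader will extract, so the full DICOM round
trip is self-consistent. Activity is pre-quantised to the 16-bit rescale
grid used by the DICOM writer, making write→read bit-exact.

Default grids are a scaled-down stand-in for a whole-body acquisition
(PET 64×64×48 at 2.7344×2.7344×3.27 mm; CT at twice the in-plane
resolution), keeping tests fast; any size can be requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np

from . import io_dicom
from .core import (BinaryMask, ContourSet, InputError, LesionStats,
                   ParameterError, SUVFactors, Units, VolumeImage)
from .lesion import quantify_lesions

PET_SPACING = (2.7344, 2.7344, 3.27)

DEFAULT_FACTORS = SUVFactors(
    injected_dose=3.7e8,
    half_life=6586.2,
    injection_time=datetime(2020, 1, 1, 10, 0, 0),
    acquisition_time=datetime(2020, 1, 1, 11, 0, 0),
    patient_weight=70.0,
)


@dataclass(frozen=True)
class Cylinder:
    """A z-aligned bone: cortical shell around marrow."""

    centre_xy: tuple[float, float]
    radius_mm: float
    z_range: tuple[float, float]
    cortical_hu: float = 700.0
    marrow_hu: float = 50.0
    shell_mm: float = 5.0

    def contains_sphere(self, centre, radius) -> bool:
        cx, cy = self.centre_xy
        d = float(np.hypot(centre[0] - cx, centre[1] - cy))
        return (d + radius <= self.radius_mm
                and self.z_range[0] + radius <= centre[2]
                and centre[2] <= self.z_range[1] - radius)

    def paint(self, hu, X, Y, Z) -> None:
        cx, cy = self.centre_xy
        r2 = (X - cx) ** 2 + (Y - cy) ** 2
        in_z = (Z >= self.z_range[0]) & (Z <= self.z_range[1])
        outer = (r2 <= self.radius_mm ** 2) & in_z
        inner = (r2 <= max(self.radius_mm - self.shell_mm, 0.0) ** 2) & in_z
        hu[outer] = self.cortical_hu
        hu[inner] = self.marrow_hu


@dataclass(frozen=True)
class Ellipsoid:
    """A solid bone blob of uniform HU."""

    centre: tuple[float, float, float]
    radii: tuple[float, float, float]
    hu: float = 400.0

    def contains_sphere(self, centre, radius) -> bool:
        # conservative: shrink each semi-axis by the sphere radius
        shrunk = [max(r - radius, 0.0) for r in self.radii]
        if min(shrunk) == 0.0:
            return False
        d = sum(((c - cc) / s) ** 2
                for c, cc, s in zip(centre, self.centre, shrunk))
        return d <= 1.0

    def paint(self, hu, X, Y, Z) -> None:
        d = ((X - self.centre[0]) / self.radii[0]) ** 2 \
            + ((Y - self.centre[1]) / self.radii[1]) ** 2 \
            + ((Z - self.centre[2]) / self.radii[2]) ** 2
        hu[d <= 1.0] = self.hu


@dataclass(frozen=True)
class Organ:
    """An extra-osseous high-uptake sphere (bladder, kidney, brain...)."""

    centre: tuple[float, float, float]
    radius_mm: float
    suv: float


@dataclass(frozen=True)
class Lesion:
    """A spherical osseous lesion with a uniform SUV plateau."""

    centre: tuple[float, float, float]
    radius_mm: float
    suv: float
    inside_bone: bool = True


@dataclass
class PhantomSpec:
    shape_pet: tuple[int, int, int] = (64, 64, 48)
    spacing_pet: tuple[float, float, float] = PET_SPACING
    ct_inplane_factor: int = 2
    skeleton: list = field(default_factory=list)
    organs: list[Organ] = field(default_factory=list)
    lesions: list[Lesion] = field(default_factory=list)
    background_suv: float = 1.0
    soft_tissue_hu: float = 40.0
    noise_suv: float = 0.0
    noise_hu: float = 0.0
    suv_factors: SUVFactors = field(default_factory=lambda: DEFAULT_FACTORS)
    seed: int = 0

    @property
    def fov_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape_pet, self.spacing_pet))

    def pet_grid(self) -> tuple[tuple, tuple, tuple]:
        return self.shape_pet, self.spacing_pet, (0.0, 0.0, 0.0)

    def ct_grid(self) -> tuple[tuple, tuple, tuple]:
        f = self.ct_inplane_factor
        shape = (self.shape_pet[0] * f, self.shape_pet[1] * f,
                 self.shape_pet[2])
        spacing = (self.spacing_pet[0] / f, self.spacing_pet[1] / f,
                   self.spacing_pet[2])
        # half-voxel shift so the CT and PET fields of view coincide
        origin = (-(self.spacing_pet[0] - spacing[0]) / 2,
                  -(self.spacing_pet[1] - spacing[1]) / 2, 0.0)
        return shape, spacing, origin

    def validate(self) -> None:
        fov = self.fov_mm
        for lesion in self.lesions:
            for c, extent in zip(lesion.centre, fov):
                if c - lesion.radius_mm < 0 or c + lesion.radius_mm > extent:
                    raise ParameterError(
                        f"lesion at {lesion.centre} (r={lesion.radius_mm} mm)"
                        " extends outside the phantom grid")
            if lesion.radius_mm <= 0:
                raise ParameterError("lesion radius must be positive")
            if lesion.inside_bone and not any(
                    b.contains_sphere(lesion.centre, lesion.radius_mm)
                    for b in self.skeleton):
                raise ParameterError(
                    f"lesion at {lesion.centre} is flagged inside-bone but "
                    "lies outside every skeleton primitive")


@dataclass
class PhantomResult:
    ct: VolumeImage                 # HU, CT grid
    pet: VolumeImage                # Bq/ml (quantised), PET grid
    suv: VolumeImage                # designed noiseless SUV map, PET grid
    truth_labels: VolumeImage       # lesion ground truth, PET grid
    truth_stats: list[LesionStats]
    truth_bone: BinaryMask          # analytic skeleton on the PET grid
    contours: ContourSet
    factors: SUVFactors
    rescale_slope: float


def _mesh(shape, spacing, origin):
    ax = [origin[a] + np.arange(shape[a]) * spacing[a] for a in range(3)]
    return np.meshgrid(*ax, indexing="ij")


def _sphere(X, Y, Z, centre, radius) -> np.ndarray:
    return ((X - centre[0]) ** 2 + (Y - centre[1]) ** 2
            + (Z - centre[2]) ** 2) <= radius ** 2


def _circle_polygon(cx: float, cy: float, r: float, z: float,
                    n_vertices: int = 64) -> np.ndarray:
    angles = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    return np.column_stack([cx + r * np.cos(angles),
                            cy + r * np.sin(angles),
                            np.full(n_vertices, z)])


def generate_phantom(spec: PhantomSpec) -> PhantomResult:
    """Build the CT, PET and ground-truth volumes described by a spec.

    Deterministic for a fixed seed. Truth statistics are computed from the
    voxelised lesion geometry against the noiseless SUV map.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    # ---- CT on its own (finer) grid
    ct_shape, ct_spacing, ct_origin = spec.ct_grid()
    Xc, Yc, Zc = _mesh(ct_shape, ct_spacing, ct_origin)
    hu = np.full(ct_shape, -1000.0)
    fov = spec.fov_mm
    body_centre = (fov[0] / 2, fov[1] / 2)
    body_radius = 0.48 * min(fov[0], fov[1])
    body_ct = ((Xc - body_centre[0]) ** 2
               + (Yc - body_centre[1]) ** 2) <= body_radius ** 2
    hu[body_ct] = spec.soft_tissue_hu
    for bone in spec.skeleton:
        bone.paint(hu, Xc, Yc, Zc)
    if spec.noise_hu > 0:
        hu = hu + rng.normal(0.0, spec.noise_hu, ct_shape)
    ct = VolumeImage(hu, ct_spacing, ct_origin, Units.HU)

    # ---- SUV design on the PET grid
    pet_shape, pet_spacing, pet_origin = spec.pet_grid()
    Xp, Yp, Zp = _mesh(pet_shape, pet_spacing, pet_origin)
    suv = np.zeros(pet_shape)
    body_pet = ((Xp - body_centre[0]) ** 2
                + (Yp - body_centre[1]) ** 2) <= body_radius ** 2
    suv[body_pet] = spec.background_suv
    for organ in spec.organs:
        suv[_sphere(Xp, Yp, Zp, organ.centre, organ.radius_mm)] = organ.suv

    labels = np.zeros(pet_shape, dtype=np.int32)
    for idx, lesion in enumerate(spec.lesions, start=1):
        inside = _sphere(Xp, Yp, Zp, lesion.centre, lesion.radius_mm)
        suv[inside] = lesion.suv
        labels[inside] = idx
    truth_labels = VolumeImage(labels, pet_spacing, pet_origin, Units.LABEL)
    suv_clean = VolumeImage(suv.copy(), pet_spacing, pet_origin, Units.SUV_BW)
    truth_stats = quantify_lesions(truth_labels, suv_clean)

    # ---- analytic skeleton rendered directly on the PET grid
    hu_pet = np.full(pet_shape, -1000.0)
    for bone in spec.skeleton:
        bone.paint(hu_pet, Xp, Yp, Zp)
    bone_pet = hu_pet > -1000.0
    truth_bone = BinaryMask(bone_pet, pet_spacing, pet_origin)

    # ---- noise, then back-conversion to quantised activity
    if spec.noise_suv > 0:
        suv = np.clip(suv + rng.normal(0.0, spec.noise_suv, pet_shape), 0, None)
    suv_vol = VolumeImage(suv, pet_spacing, pet_origin, Units.SUV_BW)
    activity = io_dicom.from_suv_map(suv_vol, spec.suv_factors)
    slope = io_dicom.choose_pet_rescale(float(activity.data.max()))
    quantised = np.round(activity.data / slope) * slope
    pet = VolumeImage(quantised, pet_spacing, pet_origin, Units.BQML)

    # ---- analytic lesion contours (one circle per intersecting slice)
    structures = []
    for idx, lesion in enumerate(spec.lesions, start=1):
        cx, cy, cz = lesion.centre
        polys = []
        for k in range(pet_shape[2]):
            z = pet_origin[2] + k * pet_spacing[2]
            dz = z - cz
            if abs(dz) >= lesion.radius_mm:
                continue
            rr = float(np.sqrt(lesion.radius_mm ** 2 - dz ** 2))
            polys.append(_circle_polygon(cx, cy, rr, z))
        structures.append((f"lesion_{idx}", polys))
    contours = ContourSet(structures)

    return PhantomResult(ct=ct, pet=pet, suv=suv_clean,
                         truth_labels=truth_labels, truth_stats=truth_stats,
                         truth_bone=truth_bone, contours=contours,
                         factors=spec.suv_factors, rescale_slope=slope)


def write_phantom_dicom(result: PhantomResult, directory) -> None:
    """Write a phantom as PET + CT DICOM series, RTSTRUCT and truth NIfTI."""
    from pathlib import Path
    directory = Path(directory)
    frame = io_dicom.write_ct_series(result.ct, directory / "ct")
    io_dicom.write_pet_series(result.pet, result.factors, directory / "pet",
                              frame_of_reference=frame,
                              rescale_slope=result.rescale_slope)
    contours = ContourSet(result.contours.structures, frame)
    io_dicom.write_rtstruct(contours, directory / "rtstruct.dcm")
    io_dicom.write_nifti(result.truth_labels,
                         directory / "truth_labels.nii.gz")
    io_dicom.write_nifti(result.suv, directory / "truth_suv.nii.gz",
                         suv_factors=result.factors)


# --------------------------------------------------------------- presets

def _default_skeleton(spec_fov) -> list:
    zmax = spec_fov[2]
    return [
        Cylinder(centre_xy=(87.0, 60.0), radius_mm=14.0,
                 z_range=(0.0, zmax)),
        Cylinder(centre_xy=(45.0, 120.0), radius_mm=13.0,
                 z_range=(0.0, zmax)),
    ]


def _default_organs() -> list[Organ]:
    return [
        Organ(centre=(130.0, 120.0, 60.0), radius_mm=12.0, suv=8.0),
        Organ(centre=(35.0, 55.0, 110.0), radius_mm=10.0, suv=6.0),
    ]


_OLIGO_LESIONS = [
    Lesion(centre=(87.0, 60.0, 30.0), radius_mm=6.0, suv=4.5),
    Lesion(centre=(86.0, 61.0, 80.0), radius_mm=5.0, suv=3.8),
    Lesion(centre=(45.0, 120.0, 120.0), radius_mm=6.0, suv=5.5),
]

_WIDESPREAD_LESIONS = _OLIGO_LESIONS + [
    Lesion(centre=(88.0, 59.0, 130.0), radius_mm=4.5, suv=6.0),
    Lesion(centre=(87.0, 61.0, 105.0), radius_mm=4.0, suv=4.0),
    Lesion(centre=(45.0, 119.0, 40.0), radius_mm=7.0, suv=3.6),
    Lesion(centre=(46.0, 121.0, 75.0), radius_mm=5.0, suv=5.0),
]


def preset_spec(name: str = "oligo", seed: int = 0,
                noise_suv: float = 0.0, noise_hu: float = 0.0) -> PhantomSpec:
    """A ready-made phantom: ``oligo`` (3 lesions) or ``widespread`` (7)."""
    spec = PhantomSpec(seed=seed, noise_suv=noise_suv, noise_hu=noise_hu)
    spec.skeleton = _default_skeleton(spec.fov_mm)
    spec.organs = _default_organs()
    if name == "oligo":
        spec.lesions = list(_OLIGO_LESIONS)
    elif name == "widespread":
        spec.lesions = list(_WIDESPREAD_LESIONS)
    else:
        raise ParameterError(f"unknown preset {name!r}")
    spec.validate()
    return spec


def random_cohort(n: int, seed: int = 0, suv_range=(3.5, 6.0),
                  radius_range=(4.0, 7.0), n_lesions_range=(2, 6),
                  noise_suv: float = 0.0,
                  noise_hu: float = 0.0) -> list[PhantomSpec]:
    """A cohort of phantoms with randomised lesion layouts.

    Lesion centres are drawn inside the skeleton primitives (rejection
    sampling on the inside-bone condition), sizes and SUV plateaus
    uniformly within the given ranges. Deterministic for a fixed seed.
    """
    if n < 1:
        raise ParameterError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n):
        spec = PhantomSpec(seed=int(rng.integers(0, 2 ** 31)),
                           noise_suv=noise_suv, noise_hu=noise_hu)
        spec.skeleton = _default_skeleton(spec.fov_mm)
        spec.organs = _default_organs()
        n_lesions = int(rng.integers(n_lesions_range[0],
                                     n_lesions_range[1] + 1))
        zmax = spec.fov_mm[2]
        lesions: list[Lesion] = []
        attempts = 0
        while len(lesions) < n_lesions and attempts < 1000:
            attempts += 1
            bone = spec.skeleton[int(rng.integers(len(spec.skeleton)))]
            radius = float(rng.uniform(*radius_range))
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0, max(bone.radius_mm - radius, 0.0))
            centre = (bone.centre_xy[0] + rad * np.cos(ang),
                      bone.centre_xy[1] + rad * np.sin(ang),
                      float(rng.uniform(radius + 2, zmax - radius - 2)))
            if not bone.contains_sphere(centre, radius):
                continue
            # keep lesions well separated so each stays one component
            if any(np.linalg.norm(np.subtract(centre, l.centre))
                   < l.radius_mm + radius + 12.0 for l in lesions):
                continue
            lesions.append(Lesion(centre=centre, radius_mm=radius,
                                  suv=float(rng.uniform(*suv_range))))
        if not lesions:
            raise InputError("failed to place any lesion; widen the ranges")
        spec.lesions = lesions
        spec.validate()
        cohort.append(spec)
    return cohort
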