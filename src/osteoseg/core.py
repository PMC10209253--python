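"""Core value types shared by every pipeline stage.

Conventions fixed here, once:

* volumes are indexed ``data[x, y, z]`` with 0-based voxel indices;
* the physical position (mm) of voxel ``(i, j, k)`` is
  ``origin + index * spacing`` (axis-aligned grids only);
* voxel volume is reported in millilitres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Sequence

import numpy as np

__all__ = [
    "Units",
    "VolumeImage",
    "BinaryMask",
    "SUVFactors",
    "ContourSet",
    "LesionStats",
    "OsteosegError",
    "InputError",
    "MetadataError",
    "UnitError",
    "GeometryError",
    "ParameterError",
    "UndefinedResultError",
]

# FDG physical half-life in seconds, used only as a documented fallback.
FDG_HALF_LIFE_S = 6586.2


class OsteosegError(Exception):
    """Base class for all package errors."""


class InputError(OsteosegError):
    """Malformed or inconsistent input data (missing slices, mixed series...)."""


class MetadataError(OsteosegError):
    """A required header field is absent or unparseable."""


class UnitError(OsteosegError):
    """An operation received a volume in the wrong value units."""


class GeometryError(OsteosegError):
    """Grids or frames of reference do not match."""


class ParameterError(OsteosegError):
    """A caller-supplied parameter is out of its valid range."""


class UndefinedResultError(OsteosegError):
    """The requested statistic is mathematically undefined for this input."""


class Units:
    """String constants for the value units a :class:`VolumeImage` may carry."""

    HU = "HU"
    BQML = "BQML"
    SUV_BW = "SUV_BW"
    BINARY = "BINARY"
    LABEL = "LABEL"
    UNKNOWN = "UNKNOWN"

    ALL = frozenset({HU, BQML, SUV_BW, BINARY, LABEL, UNKNOWN})


@dataclass
class VolumeImage:
    """A 3-D scalar grid with voxel spacing (mm), origin (mm) and value units.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar values, indexed ``[x, y, z]``.
    spacing : sequence of 3 floats
        Voxel size along x, y, z in millimetres; all strictly positive.
    origin : sequence of 3 floats
        Physical position (mm) of voxel ``(0, 0, 0)``.
    units : str
        One of :class:`Units`.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    units: str = Units.UNKNOWN

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise InputError(f"expected a 3-D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise InputError("spacing and origin must have 3 components")
        if any(s <= 0 for s in self.spacing):
            raise InputError(f"voxel spacing must be positive, got {self.spacing}")
        if self.units not in Units.ALL:
            raise UnitError(f"unknown units {self.units!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (mm^3 / 1000)."""
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    def index_to_mm(self, index: Sequence[float]) -> np.ndarray:
        """Physical coordinates (mm) of a voxel index triple."""
        return np.asarray(self.origin) + np.asarray(index) * np.asarray(self.spacing)

    def mm_to_index(self, mm: Sequence[float]) -> np.ndarray:
        """Continuous voxel index of a physical point (mm)."""
        return (np.asarray(mm) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def same_grid(self, other: "VolumeImage", atol: float = 1e-3) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def with_data(self, data: np.ndarray, units: str | None = None) -> "VolumeImage":
        """A copy of this grid carrying new voxel values."""
        return VolumeImage(data, self.spacing, self.origin,
                           self.units if units is None else units)


class BinaryMask(VolumeImage):
    """A {0,1} volume on a reference grid."""

    def __post_init__(self) -> None:
        self.units = Units.BINARY
        super().__post_init__()
        self.data = np.asarray(self.data).astype(bool)

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())


@dataclass
class SUVFactors:
    """Everything needed for body-weight SUV conversion of a PET volume.

    ``injected_dose`` is in Bq at injection time, ``half_life`` in seconds
    and ``patient_weight`` in kg. ``decay_reference`` records what time the
    stored activity was decay-corrected to: ``"START"`` (series/acquisition
    start, the vendor default) or ``"ADMIN"`` (injection time, i.e. no
    further decay correction is applied here).
    """

    injected_dose: float
    half_life: float
    injection_time: datetime
    acquisition_time: datetime
    patient_weight: float
    decay_reference: str = "START"

    def __post_init__(self) -> None:
        if self.injected_dose <= 0:
            raise MetadataError("injected_dose must be positive")
        if self.half_life <= 0:
            raise MetadataError("half_life must be positive")
        if self.patient_weight <= 0:
            raise MetadataError("patient_weight must be positive")
        if self.decay_reference not in ("START", "ADMIN"):
            raise MetadataError(
                f"decay_reference must be START or ADMIN, got {self.decay_reference!r}")
        # Timestamps that pair an evening injection with a past-midnight scan
        # come out negative once; a single +24 h fixes them, anything more is
        # genuinely inconsistent.
        if self.acquisition_time < self.injection_time:
            shifted = self.acquisition_time + timedelta(hours=24)
            if shifted >= self.injection_time:
                self.acquisition_time = shifted
            if self.acquisition_time < self.injection_time:
                raise MetadataError(
                    "acquisition_time precedes injection_time by more than 24 h")

    @property
    def decay_interval_s(self) -> float:
        """Seconds from injection to the decay-correction reference time."""
        if self.decay_reference == "ADMIN":
            return 0.0
        return (self.acquisition_time - self.injection_time).total_seconds()

    @property
    def decayed_dose(self) -> float:
        """Injected dose decayed to the reference time, in Bq."""
        return self.injected_dose * 2.0 ** (-self.decay_interval_s / self.half_life)


@dataclass
class ContourSet:
    """Named planar polygons in physical coordinates (mm).

    ``structures`` maps a structure name to a list of polygons; each polygon
    is an (N, 3) array of vertices lying on one axial plane.
    """

    structures: list[tuple[str, list[np.ndarray]]]
    frame_of_reference: str = ""

    def __post_init__(self) -> None:
        for name, polys in self.structures:
            for poly in polys:
                p = np.asarray(poly)
                if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] < 3:
                    raise InputError(
                        f"structure {name!r}: polygons need >= 3 (x,y,z) vertices")


@dataclass(frozen=True)
class LesionStats:
    """Per-lesion quantification record."""

    label: int
    volume_ml: float
    suv_mean: float
    suv_max: float
    max_coord: tuple[int, int, int]
    max_coord_mm: tuple[float, float, float]
    voxel_count: int = field(default=0)
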