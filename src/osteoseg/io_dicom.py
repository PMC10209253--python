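"""Reading and writing of PET/CT DICOM series, RTSTRUCT contours and NIfTI.

The DICOM layer is backed by the package's own explicit-VR codec
(:mod:`osteoseg._dicom`); NIfTI goes through nibabel with a JSON sidecar
carrying value units and SUV factors (NIfTI itself has no slot for either).
"""

from __future__ import annotations

import json
import logging
import warnings
from datetime import datetime
from pathlib import Path

import nibabel as nib
import numpy as np
from skimage import measure

from . import _dicom
from ._dicom import Dataset
from .core import (FDG_HALF_LIFE_S, BinaryMask, ContourSet, GeometryError,
                   InputError, MetadataError, SUVFactors, UnitError, Units,
                   VolumeImage)

log = logging.getLogger(__name__)

_MODALITY_CODES = {"PET": "PT", "PT": "PT", "CT": "CT"}


# ------------------------------------------------------------ DICOM series

def _pixel_array(ds: Dataset) -> np.ndarray:
    rows = int(ds["Rows"])
    cols = int(ds["Columns"])
    signed = int(ds.get("PixelRepresentation", 0)) == 1
    dtype = np.int16 if signed else np.uint16
    raw = ds["PixelData"]
    arr = np.frombuffer(raw, dtype="<" + np.dtype(dtype).str[1:],
                        count=rows * cols)
    return arr.reshape(rows, cols)


def read_dicom_series(directory: str | Path, modality: str) -> VolumeImage:
    """Read one DICOM series of the given modality into a volume.

    Slices are sorted by their physical axial position regardless of file
    names. CT values are rescaled to HU, PET values to activity
    concentration (Bq/ml), via each slice's rescale slope/intercept.

    The returned volume carries two extra attributes: ``meta`` (the header
    dataset of the first slice, for SUV-factor extraction) and
    ``frame_of_reference``.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise InputError(f"not a directory: {directory}")
    code = _MODALITY_CODES.get(modality.upper())
    if code is None:
        raise InputError(f"unsupported modality {modality!r}")

    slices = []
    for path in sorted(directory.iterdir()):
        if path.is_file() and _dicom.is_dicom(path):
            ds = _dicom.dcmread(path)
            if ds.get("Modality") == code:
                slices.append(ds)
    if not slices:
        raise InputError(f"no {modality} DICOM slices found in {directory}")

    series_uids = {ds.get("SeriesInstanceUID") for ds in slices}
    if len(series_uids) != 1:
        raise InputError(
            f"{directory} contains {len(series_uids)} {modality} series; "
            "expected exactly one")

    orient = slices[0].get("ImageOrientationPatient", [1, 0, 0, 0, 1, 0])
    if not np.allclose(orient, [1, 0, 0, 0, 1, 0], atol=1e-6):
        raise GeometryError(f"unsupported image orientation {orient}; "
                            "only axis-aligned axial series are handled")

    slices.sort(key=lambda ds: float(ds["ImagePositionPatient"][2]))
    z_positions = np.array([float(ds["ImagePositionPatient"][2])
                            for ds in slices])
    if len(slices) > 1:
        gaps = np.diff(z_positions)
        if gaps.max() - gaps.min() > 1e-3 or gaps.min() <= 0:
            raise InputError(
                f"non-uniform slice gap in {directory}: spacing ranges "
                f"{gaps.min():.4f}-{gaps.max():.4f} mm (missing or "
                "duplicated slice?)")
        dz = float(gaps.mean())
    else:
        dz = float(slices[0].get("SliceThickness", 1.0))

    first = slices[0]
    pixel_spacing = first["PixelSpacing"]  # (row=y, col=x)
    sy, sx = float(pixel_spacing[0]), float(pixel_spacing[1])
    ipp = first["ImagePositionPatient"]

    planes = []
    for ds in slices:
        if "RescaleSlope" not in ds:
            raise MetadataError("missing RescaleSlope (0028,1053)")
        if "RescaleIntercept" not in ds:
            raise MetadataError("missing RescaleIntercept (0028,1052)")
        slope = float(ds["RescaleSlope"])
        intercept = float(ds["RescaleIntercept"])
        planes.append(_pixel_array(ds).astype(np.float64) * slope + intercept)

    # stack: plane is (rows=y, cols=x) -> transpose to (x, y)
    data = np.stack([p.T for p in planes], axis=2)

    if code == "CT":
        units = Units.HU
    else:
        pet_units = first.get("Units", None)
        if pet_units is None:
            warnings.warn("PET series lacks the Units tag (0054,1001); "
                          "assuming BQML", stacklevel=2)
            pet_units = "BQML"
        if pet_units != "BQML":
            raise UnitError(f"unsupported PET units {pet_units!r}; "
                            "expected BQML")
        units = Units.BQML

    vol = VolumeImage(data, (sx, sy, dz),
                      (float(ipp[0]), float(ipp[1]), float(z_positions[0])),
                      units)
    vol.meta = first  # type: ignore[attr-defined]
    vol.frame_of_reference = first.get("FrameOfReferenceUID", "")  # type: ignore[attr-defined]
    return vol


def _parse_tm(value: str) -> tuple[int, int, float]:
    value = str(value).strip()
    if len(value) < 6:
        raise MetadataError(f"unparseable DICOM time {value!r}")
    return int(value[0:2]), int(value[2:4]), float(value[4:])


def _format_tm(t: datetime) -> str:
    return t.strftime("%H%M%S.%f")


def extract_suv_factors(pet_header: Dataset) -> SUVFactors:
    """Pull dose, half-life, times and weight out of a PET slice header.

    The half-life falls back to the FDG physical constant (with a warning)
    when the header omits it; every other field is mandatory. Injection and
    acquisition clock times are paired on the acquisition date; a scan that
    crosses midnight is repaired inside :class:`SUVFactors`.
    """
    weight = pet_header["PatientWeight"]
    seq = pet_header["RadiopharmaceuticalInformationSequence"]
    if not seq:
        raise MetadataError("empty RadiopharmaceuticalInformationSequence")
    rp = seq[0]
    dose = rp["RadionuclideTotalDose"]
    half_life = rp.get("RadionuclideHalfLife")
    if half_life is None:
        warnings.warn("RadionuclideHalfLife absent; assuming FDG "
                      f"({FDG_HALF_LIFE_S} s)", stacklevel=2)
        half_life = FDG_HALF_LIFE_S

    date_str = str(pet_header.get("AcquisitionDate", "20000101"))
    year, month, day = int(date_str[:4]), int(date_str[4:6]), int(date_str[6:8])

    ih, im, isec = _parse_tm(rp["RadiopharmaceuticalStartTime"])
    ah, am, asec = _parse_tm(pet_header["AcquisitionTime"])
    injection = datetime(year, month, day, ih, im, int(isec),
                         int(round((isec % 1) * 1e6)))
    acquisition = datetime(year, month, day, ah, am, int(asec),
                           int(round((asec % 1) * 1e6)))

    decay_ref = str(pet_header.get("DecayCorrection", "START")).upper()
    decay_ref = "ADMIN" if decay_ref == "ADMIN" else "START"

    return SUVFactors(
        injected_dose=float(dose),
        half_life=float(half_life),
        injection_time=injection,
        acquisition_time=acquisition,
        patient_weight=float(weight),
        decay_reference=decay_ref,
    )


# ------------------------------------------------------------ SUV mapping

def to_suv_map(pet: VolumeImage, factors: SUVFactors) -> VolumeImage:
    """Convert an activity-concentration volume (Bq/ml) to body-weight SUV.

    SUV_bw(v) = C(v) / ( D * 2^(-dt/T_half) / (1000 * W) )

    with C in Bq/ml, D the injected dose in Bq, dt the decay interval in
    seconds and W the patient weight in kg (1000*W = weight in grams, so the
    result is dimensionless under the 1 g/ml tissue-density convention).
    """
    if pet.units != Units.BQML:
        raise UnitError(f"to_suv_map expects BQML input, got {pet.units}")
    if factors.decay_interval_s < 0:
        raise MetadataError("negative decay interval")
    denom = factors.decayed_dose / (1000.0 * factors.patient_weight)
    return pet.with_data(pet.data / denom, Units.SUV_BW)


def from_suv_map(suv: VolumeImage, factors: SUVFactors) -> VolumeImage:
    """Inverse of :func:`to_suv_map`: SUV back to Bq/ml."""
    if suv.units != Units.SUV_BW:
        raise UnitError(f"from_suv_map expects SUV_BW input, got {suv.units}")
    denom = factors.decayed_dose / (1000.0 * factors.patient_weight)
    return suv.with_data(suv.data * denom, Units.BQML)


# -------------------------------------------------------- contour geometry

def _points_in_polygon(px: np.ndarray, py: np.ndarray,
                       poly: np.ndarray) -> np.ndarray:
    """Vectorised even-odd (ray casting) point-in-polygon test."""
    inside = np.zeros(px.shape, dtype=bool)
    x1, y1 = poly[-1, 0], poly[-1, 1]
    for x2, y2 in poly[:, :2]:
        crosses = (y1 > py) != (y2 > py)
        if np.any(crosses):
            with np.errstate(divide="ignore", invalid="ignore"):
                x_at = (x2 - x1) * (py - y1) / (y2 - y1) + x1
            inside ^= crosses & (px < x_at)
        x1, y1 = x2, y2
    return inside


def rasterise_contours(contours: ContourSet, grid: VolumeImage,
                       frame_of_reference: str | None = None) -> VolumeImage:
    """Rasterise planar polygons onto the grid as an integer label map.

    Structure i (1-based) becomes label i; a voxel belongs to a structure if
    its centre lies inside the polygon on that axial slice (even-odd rule,
    so an inner ring subtracts a hole). Overlapping structures are resolved
    later-structure-wins.
    """
    grid_for = frame_of_reference
    if grid_for is None:
        grid_for = getattr(grid, "frame_of_reference", "")
    if grid_for and contours.frame_of_reference and \
            grid_for != contours.frame_of_reference:
        raise GeometryError(
            f"frame of reference mismatch: grid {grid_for!r} vs contours "
            f"{contours.frame_of_reference!r}")

    nx, ny, nz = grid.shape
    ox, oy, oz = grid.origin
    sx, sy, sz = grid.spacing
    xs = ox + np.arange(nx) * sx
    ys = oy + np.arange(ny) * sy
    px, py = np.meshgrid(xs, ys, indexing="ij")

    labels = np.zeros(grid.shape, dtype=np.int32)
    for idx, (_name, polys) in enumerate(contours.structures, start=1):
        slice_hits: dict[int, np.ndarray] = {}
        for poly in polys:
            poly = np.asarray(poly, dtype=float)
            z = float(poly[:, 2].mean())
            k = int(round((z - oz) / sz))
            if k < 0 or k >= nz or abs(z - (oz + k * sz)) > sz / 2 + 1e-6:
                raise GeometryError(
                    f"contour plane z={z:.3f} mm does not coincide with an "
                    "axial slice of the target grid")
            hit = _points_in_polygon(px, py, poly)
            if k in slice_hits:
                slice_hits[k] ^= hit  # even-odd across rings
            else:
                slice_hits[k] = hit
        for k, hit in slice_hits.items():
            labels[:, :, k][hit] = idx
    out = grid.with_data(labels, Units.LABEL)
    return out


def extract_contours(labels: VolumeImage,
                     frame_of_reference: str = "") -> ContourSet:
    """Trace axial iso-contours of each label (inverse of rasterisation).

    Contours are taken at the 0.5 level of each label's binary mask, so
    they run between voxel centres; rasterising them back reproduces the
    label map exactly.
    """
    ox, oy, oz = labels.origin
    sx, sy, sz = labels.spacing
    structures = []
    max_label = int(labels.data.max()) if labels.data.size else 0
    for lab in range(1, max_label + 1):
        mask = labels.data == lab
        polys = []
        for k in range(labels.shape[2]):
            plane = mask[:, :, k]
            if not plane.any():
                continue
            padded = np.pad(plane.astype(float), 1)
            for contour in measure.find_contours(padded, 0.5):
                # drop the duplicated closing vertex; shift for the pad
                verts = contour[:-1] - 1.0
                poly = np.column_stack([
                    ox + verts[:, 0] * sx,
                    oy + verts[:, 1] * sy,
                    np.full(len(verts), oz + k * sz),
                ])
                if len(poly) >= 3:
                    polys.append(poly)
        structures.append((f"structure_{lab}", polys))
    return ContourSet(structures, frame_of_reference or
                      getattr(labels, "frame_of_reference", ""))


# ------------------------------------------------------------------ NIfTI

def _sidecar_path(path: str | Path) -> Path:
    path = Path(path)
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_name(name + ".json")


def _factors_to_json(factors: SUVFactors) -> dict:
    return {
        "injected_dose": factors.injected_dose,
        "half_life": factors.half_life,
        "injection_time": factors.injection_time.isoformat(),
        "acquisition_time": factors.acquisition_time.isoformat(),
        "patient_weight": factors.patient_weight,
        "decay_reference": factors.decay_reference,
    }


def factors_from_json(payload: dict) -> SUVFactors:
    return SUVFactors(
        injected_dose=float(payload["injected_dose"]),
        half_life=float(payload["half_life"]),
        injection_time=datetime.fromisoformat(payload["injection_time"]),
        acquisition_time=datetime.fromisoformat(payload["acquisition_time"]),
        patient_weight=float(payload["patient_weight"]),
        decay_reference=payload.get("decay_reference", "START"),
    )


def write_nifti(image: VolumeImage, path: str | Path,
                suv_factors: SUVFactors | None = None) -> None:
    """Write a volume as NIfTI plus a JSON sidecar holding the units."""
    affine = np.diag(list(image.spacing) + [1.0])
    affine[:3, 3] = image.origin
    data = np.asarray(image.data)
    if data.dtype == bool:  # NIfTI has no boolean type
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, affine), str(path))
    sidecar = {"units": image.units}
    if suv_factors is not None:
        sidecar["suv_factors"] = _factors_to_json(suv_factors)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_nifti(path: str | Path) -> VolumeImage:
    """Read a NIfTI volume; units come from the sidecar (UNKNOWN if absent)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    affine = img.affine
    spacing = tuple(float(s) for s in np.abs(np.diag(affine)[:3]))
    origin = tuple(float(o) for o in affine[:3, 3])
    units = Units.UNKNOWN
    sidecar = _sidecar_path(path)
    factors = None
    if sidecar.exists():
        payload = json.loads(sidecar.read_text())
        units = payload.get("units", Units.UNKNOWN)
        if "suv_factors" in payload:
            factors = factors_from_json(payload["suv_factors"])
    else:
        warnings.warn(f"no JSON sidecar for {path}; units recorded as "
                      "unknown", stacklevel=2)
        log.warning("no JSON sidecar for %s; units unknown", path)
    vol = VolumeImage(data, spacing, origin, units)
    if factors is not None:
        vol.suv_factors = factors  # type: ignore[attr-defined]
    return vol


# ----------------------------------------------------------- DICOM export

def choose_pet_rescale(max_value: float) -> float:
    """A rescale slope with a short, exactly round-tripping decimal form."""
    return float(f"{max(max_value, 1e-9) / 32000.0:.6e}")


def _base_slice(modality: str, sop_class: str, series_uid: str,
                study_uid: str, frame_uid: str, k: int,
                image: VolumeImage) -> Dataset:
    ds = Dataset()
    ds.set("SOPClassUID", sop_class)
    ds.set("SOPInstanceUID", _dicom.new_uid())
    ds.set("Modality", modality)
    ds.set("StudyInstanceUID", study_uid)
    ds.set("SeriesInstanceUID", series_uid)
    ds.set("SeriesNumber", 1)
    ds.set("InstanceNumber", k + 1)
    ds.set("FrameOfReferenceUID", frame_uid)
    sx, sy, sz = image.spacing
    ox, oy, oz = image.origin
    ds.set("ImagePositionPatient", [ox, oy, oz + k * sz])
    ds.set("ImageOrientationPatient", [1, 0, 0, 0, 1, 0])
    ds.set("PixelSpacing", [sy, sx])  # (row, col) order
    ds.set("SliceThickness", sz)
    ds.set("SamplesPerPixel", 1)
    ds.set("PhotometricInterpretation", "MONOCHROME2")
    ds.set("Rows", image.shape[1])
    ds.set("Columns", image.shape[0])
    ds.set("BitsAllocated", 16)
    ds.set("BitsStored", 16)
    ds.set("HighBit", 15)
    return ds


def write_ct_series(ct: VolumeImage, directory: str | Path,
                    frame_of_reference: str | None = None) -> str:
    """Write an HU volume as a CT DICOM series; returns the frame UID."""
    if ct.units != Units.HU:
        raise UnitError(f"CT writer expects HU, got {ct.units}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = _dicom.new_uid()
    study_uid = _dicom.new_uid()
    frame_uid = frame_of_reference or _dicom.new_uid()
    stored = np.round(ct.data).astype(np.int16)
    for k in range(ct.shape[2]):
        ds = _base_slice("CT", _dicom.CT_STORAGE, series_uid, study_uid,
                         frame_uid, k, ct)
        ds.set("PixelRepresentation", 1)
        ds.set("RescaleSlope", 1)
        ds.set("RescaleIntercept", 0)
        ds.set("PixelData", stored[:, :, k].T.tobytes())
        _dicom.dcmwrite(directory / f"ct_{k:04d}.dcm", ds)
    return frame_uid


def write_pet_series(pet: VolumeImage, factors: SUVFactors,
                     directory: str | Path,
                     frame_of_reference: str | None = None,
                     rescale_slope: float | None = None) -> str:
    """Write a Bq/ml volume as a PET DICOM series with SUV metadata.

    Pixel values are stored as unsigned 16-bit with a decimal rescale
    slope; quantise the volume with the same slope beforehand (see
    :func:`choose_pet_rescale`) for a bit-exact round trip.
    """
    if pet.units != Units.BQML:
        raise UnitError(f"PET writer expects BQML, got {pet.units}")
    if np.any(pet.data < 0):
        raise InputError("negative activity concentration")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    slope = rescale_slope or choose_pet_rescale(float(pet.data.max()))
    stored = np.round(pet.data / slope)
    if stored.max() > 65535:
        raise InputError("rescale slope too small for the dynamic range")
    stored = stored.astype(np.uint16)
    series_uid = _dicom.new_uid()
    study_uid = _dicom.new_uid()
    frame_uid = frame_of_reference or _dicom.new_uid()
    for k in range(pet.shape[2]):
        ds = _base_slice("PT", _dicom.PET_STORAGE, series_uid, study_uid,
                         frame_uid, k, pet)
        ds.set("PixelRepresentation", 0)
        ds.set("RescaleSlope", _dicom.format_ds(slope))
        ds.set("RescaleIntercept", 0)
        ds.set("Units", "BQML")
        ds.set("DecayCorrection", factors.decay_reference)
        ds.set("PatientWeight", factors.patient_weight)
        ds.set("AcquisitionDate",
               factors.acquisition_time.strftime("%Y%m%d"))
        ds.set("AcquisitionTime", _format_tm(factors.acquisition_time))
        rp = Dataset()
        rp.set("RadiopharmaceuticalStartTime",
               _format_tm(factors.injection_time))
        rp.set("RadionuclideTotalDose", factors.injected_dose)
        rp.set("RadionuclideHalfLife", factors.half_life)
        ds.set("RadiopharmaceuticalInformationSequence", [rp])
        ds.set("PixelData", stored[:, :, k].T.tobytes())
        _dicom.dcmwrite(directory / f"pt_{k:04d}.dcm", ds)
    return frame_uid


def write_rtstruct(contours: ContourSet, path: str | Path,
                   label: str = "OSTEOSEG") -> None:
    """Write a contour set as a DICOM RTSTRUCT file."""
    root = Dataset()
    root.set("SOPClassUID", _dicom.RTSTRUCT_STORAGE)
    root.set("SOPInstanceUID", _dicom.new_uid())
    root.set("Modality", "RTSTRUCT")
    root.set("StructureSetLabel", label)
    root.set("FrameOfReferenceUID", contours.frame_of_reference or
             _dicom.new_uid())
    roi_seq, contour_seq = [], []
    for number, (name, polys) in enumerate(contours.structures, start=1):
        roi = Dataset()
        roi.set("ROINumber", number)
        roi.set("ROIName", name)
        roi.set("ReferencedFrameOfReferenceUID", root["FrameOfReferenceUID"])
        roi_seq.append(roi)
        rc = Dataset()
        rc.set("ReferencedROINumber", number)
        items = []
        for poly in polys:
            poly = np.asarray(poly, dtype=float)
            item = Dataset()
            item.set("ContourGeometricType", "CLOSED_PLANAR")
            item.set("NumberOfContourPoints", len(poly))
            item.set("ContourData", [float(v) for v in poly.ravel()])
            items.append(item)
        rc.set("ContourSequence", items)
        contour_seq.append(rc)
    root.set("StructureSetROISequence", roi_seq)
    root.set("ROIContourSequence", contour_seq)
    _dicom.dcmwrite(path, root)


def read_rtstruct(path: str | Path) -> ContourSet:
    """Read an RTSTRUCT file back into a contour set."""
    ds = _dicom.dcmread(path)
    if ds.get("Modality") != "RTSTRUCT":
        raise InputError(f"{path} is not an RTSTRUCT object")
    names = {int(roi["ROINumber"]): str(roi["ROIName"])
             for roi in ds.get("StructureSetROISequence", [])}
    structures = []
    for rc in ds.get("ROIContourSequence", []):
        number = int(rc["ReferencedROINumber"])
        polys = []
        for item in rc.get("ContourSequence", []):
            flat = np.asarray(item["ContourData"], dtype=float)
            polys.append(flat.reshape(-1, 3))
        structures.append((names.get(number, f"roi_{number}"), polys))
    return ContourSet(structures, ds.get("FrameOfReferenceUID", ""))
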