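"""Skeleton segmentation from the grid-matched CT, and SUV masking.

The bone mask is built as::

    fill_holes( binarise( gaussian( binarise(ct >= hu_threshold) ), 0.5 ) )

i.e. HU thresholding, Gaussian edge smoothing of the binary mask with
re-binarisation at 0.5, then hole filling so marrow cavities enclosed by
cortical bone are kept inside the mask. Hole filling defaults to per-axial-
slice (2-D), which closes marrow without bridging axially separate bones;
a 3-D option is available.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import (BinaryMask, GeometryError, ParameterError, Units,
                   UnitError, VolumeImage)

DEFAULT_HU_THRESHOLD = 110.0


def bone_candidates(ct_on_pet: VolumeImage,
                    hu_threshold: float = DEFAULT_HU_THRESHOLD,
                    sigma_mm: float | None = None) -> BinaryMask:
    """The pre-hole-filling bone mask: HU threshold, then Gaussian edge
    smoothing of the binary mask re-binarised at 0.5.

    Monotone in the threshold: a higher threshold yields a subset mask.
    """
    if ct_on_pet.units != Units.HU:
        raise UnitError(f"expected HU input, got {ct_on_pet.units}")
    if sigma_mm is not None and sigma_mm < 0:
        raise ParameterError(f"sigma must be >= 0, got {sigma_mm}")
    raw = ct_on_pet.data >= hu_threshold
    if sigma_mm is None:
        sigma_vox: tuple[float, ...] = (1.0, 1.0, 1.0)
    else:
        sigma_vox = tuple(sigma_mm / s for s in ct_on_pet.spacing)
    if any(s > 0 for s in sigma_vox):
        smoothed = ndimage.gaussian_filter(raw.astype(np.float64), sigma_vox)
        mask = smoothed >= 0.5
    else:
        mask = raw
    return BinaryMask(mask, ct_on_pet.spacing, ct_on_pet.origin)


def segment_bone(ct_on_pet: VolumeImage,
                 hu_threshold: float = DEFAULT_HU_THRESHOLD,
                 sigma_mm: float | None = None,
                 fill: str = "2d") -> BinaryMask:
    """Binary skeleton mask from an HU volume on the PET grid.

    Parameters
    ----------
    hu_threshold : float
        Voxels with HU >= threshold are bone candidates (default 110 HU,
        which keeps both marrow and cortical bone).
    sigma_mm : float, optional
        Gaussian smoothing width in mm; default is one voxel per axis.
        ``0`` disables smoothing.
    fill : {"2d", "3d"}
        Hole-filling dimensionality.
    """
    if fill not in ("2d", "3d"):
        raise ParameterError(f"fill must be '2d' or '3d', got {fill!r}")
    candidates = bone_candidates(ct_on_pet, hu_threshold, sigma_mm)
    mask = candidates.data
    if fill == "3d":
        mask = ndimage.binary_fill_holes(mask)
    else:
        mask = np.stack([ndimage.binary_fill_holes(mask[:, :, k])
                         for k in range(mask.shape[2])], axis=2)
    return BinaryMask(mask, ct_on_pet.spacing, ct_on_pet.origin)


def apply_bone_mask(suv: VolumeImage, bone: BinaryMask) -> VolumeImage:
    """Zero the SUV map outside the skeleton (voxel-wise product)."""
    if suv.units != Units.SUV_BW:
        raise UnitError(f"expected SUV_BW input, got {suv.units}")
    if not suv.same_grid(bone):
        raise GeometryError("SUV map and bone mask are on different grids")
    return suv.with_data(suv.data * bone.data)


def stable_hu_threshold(ct_on_pet: VolumeImage,
                        candidates: np.ndarray | None = None,
                        sigma_mm: float | None = None) -> float:
    """Surrogate for visual HU-threshold tuning: the candidate whose mask
    volume changes least per unit threshold (flattest point of the
    volume-vs-threshold curve). A utility, not a claim about how any
    particular threshold was originally chosen."""
    if candidates is None:
        candidates = np.arange(90.0, 301.0, 10.0)
    candidates = np.asarray(sorted(candidates), dtype=float)
    if len(candidates) < 3:
        raise ParameterError("need at least 3 candidate thresholds")
    volumes = np.array([
        segment_bone(ct_on_pet, th, sigma_mm=sigma_mm).voxel_count
        for th in candidates
    ], dtype=float)
    slopes = np.abs(np.gradient(volumes, candidates))
    return float(candidates[int(np.argmin(slopes))])
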