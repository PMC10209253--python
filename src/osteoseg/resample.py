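"""Resampling of the CT volume onto the PET voxel grid.

Two modes:

* ``physical`` (default) — voxel centres are mapped through origin+spacing,
  so grids that are shifted or cover different extents land correctly;
* ``matrix`` — pure in-plane array resizing (bicubic), reproducing the
  behaviour of slice-wise image resizing without regard to physical
  coordinates; grids are assumed co-extensive.

Bicubic interpolation can overshoot near sharp edges (bone/air); with
``clamp=True`` the output is clipped to the input's value range.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import GeometryError, Units, UnitError, VolumeImage

AIR_HU = -1000.0


def resample_ct_to_pet_grid(ct: VolumeImage, pet: VolumeImage,
                            mode: str = "physical",
                            clamp: bool = True) -> VolumeImage:
    """Resample an HU volume onto the PET grid with bicubic interpolation.

    Out-of-field voxels are filled with air (−1000 HU). Returns an HU
    volume with the PET shape, spacing and origin.
    """
    if ct.units != Units.HU:
        raise UnitError(f"expected HU input, got {ct.units}")
    if mode not in ("physical", "matrix"):
        raise GeometryError(f"unknown resample mode {mode!r}")

    lo, hi = float(ct.data.min()), float(ct.data.max())

    if mode == "physical":
        nx, ny, nz = pet.shape
        # continuous CT indices of every PET voxel centre
        axes = []
        for a in range(3):
            centres_mm = pet.origin[a] + np.arange(pet.shape[a]) * pet.spacing[a]
            axes.append((centres_mm - ct.origin[a]) / ct.spacing[a])
        ix, iy, iz = np.meshgrid(*axes, indexing="ij")
        coords = np.stack([ix.ravel(), iy.ravel(), iz.ravel()])
        out = ndimage.map_coordinates(ct.data.astype(np.float64), coords,
                                      order=3,
                                      mode="nearest").reshape(nx, ny, nz)
        outside = np.zeros(out.shape, dtype=bool)
        for a, idx in enumerate((ix, iy, iz)):
            outside |= (idx < -0.5) | (idx > ct.shape[a] - 0.5)
        if clamp:
            out = np.clip(out, lo, hi)
        out[outside] = AIR_HU
        return VolumeImage(out, pet.spacing, pet.origin, Units.HU)
    else:
        data = ct.data.astype(np.float64)
        if data.shape[2] != pet.shape[2]:
            # linear z-interpolation onto the PET slice count first
            zi = np.linspace(0, data.shape[2] - 1, pet.shape[2])
            k0 = np.floor(zi).astype(int)
            k1 = np.minimum(k0 + 1, data.shape[2] - 1)
            w = zi - k0
            data = data[:, :, k0] * (1 - w) + data[:, :, k1] * w
        nx, ny = pet.shape[0], pet.shape[1]
        if (nx, ny) == data.shape[:2]:
            out = data
        else:
            # slice-wise bicubic resize via index scaling
            xi = (np.arange(nx) + 0.5) * data.shape[0] / nx - 0.5
            yi = (np.arange(ny) + 0.5) * data.shape[1] / ny - 0.5
            gx, gy = np.meshgrid(xi, yi, indexing="ij")
            coords = np.stack([gx.ravel(), gy.ravel()])
            out = np.empty((nx, ny, data.shape[2]))
            for k in range(data.shape[2]):
                out[:, :, k] = ndimage.map_coordinates(
                    data[:, :, k], coords, order=3, mode="nearest"
                ).reshape(nx, ny)

    if clamp:
        out = np.clip(out, lo, hi)
    return VolumeImage(out, pet.spacing, pet.origin, Units.HU)
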