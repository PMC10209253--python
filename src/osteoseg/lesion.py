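"""Lesion detection by absolute SUV thresholding and per-lesion statistics."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import (GeometryError, LesionStats, ParameterError, Units,
                   UnitError, VolumeImage)

DEFAULT_SUV_THRESHOLD = 3.0

_STRUCTS = {
    26: np.ones((3, 3, 3), dtype=bool),
    6: ndimage.generate_binary_structure(3, 1),
}


def segment_lesions(masked_suv: VolumeImage,
                    suv_threshold: float = DEFAULT_SUV_THRESHOLD,
                    connectivity: int = 26,
                    min_voxels: int = 1) -> VolumeImage:
    """Label connected components of {SUV >= threshold} as lesions.

    The comparison is inclusive (>=). Components are labelled 1..K in order
    of descending voxel count (ties broken by first-voxel scan order);
    components smaller than ``min_voxels`` are dropped. Input is expected
    to be bone-masked already; the function itself applies no mask.
    """
    if masked_suv.units != Units.SUV_BW:
        raise UnitError(f"expected SUV_BW input, got {masked_suv.units}")
    if suv_threshold <= 0:
        raise ParameterError(f"suv_threshold must be > 0, got {suv_threshold}")
    if connectivity not in _STRUCTS:
        raise ParameterError(f"connectivity must be 6 or 26, got {connectivity}")
    if min_voxels < 1:
        raise ParameterError(f"min_voxels must be >= 1, got {min_voxels}")

    above = masked_suv.data >= suv_threshold
    raw_labels, n = ndimage.label(above, structure=_STRUCTS[connectivity])
    out = np.zeros(raw_labels.shape, dtype=np.int32)
    if n:
        counts = np.bincount(raw_labels.ravel())[1:]  # per raw label 1..n
        order = [lab for lab in np.argsort(-counts, kind="stable") + 1
                 if counts[lab - 1] >= min_voxels]
        for new, old in enumerate(order, start=1):
            out[raw_labels == old] = new
    return masked_suv.with_data(out, Units.LABEL)


def quantify_lesions(labels: VolumeImage,
                     suv: VolumeImage) -> list[LesionStats]:
    """Per-lesion volume (ml), SUVmean, SUVmax and SUVmax location.

    volume_ml = voxel_count * voxel_volume_ml; suv_mean is the plain mean of
    the SUV values over the lesion's voxels. The SUVmax voxel is the
    arg-max; ties go to the lexicographically smallest index triple.
    """
    if labels.units != Units.LABEL:
        raise UnitError(f"expected LABEL input, got {labels.units}")
    if not labels.same_grid(suv):
        raise GeometryError("label map and SUV map are on different grids")

    stats: list[LesionStats] = []
    voxel_ml = labels.voxel_volume_ml
    max_label = int(labels.data.max()) if labels.data.size else 0
    for lab in range(1, max_label + 1):
        coords = np.argwhere(labels.data == lab)
        if len(coords) == 0:
            continue
        values = suv.data[coords[:, 0], coords[:, 1], coords[:, 2]]
        suv_max = float(values.max())
        peak_candidates = coords[values == suv_max]
        peak = min(map(tuple, peak_candidates))
        stats.append(LesionStats(
            label=lab,
            volume_ml=len(coords) * voxel_ml,
            suv_mean=float(values.mean()),
            suv_max=suv_max,
            max_coord=tuple(int(c) for c in peak),
            max_coord_mm=tuple(float(v) for v in labels.index_to_mm(peak)),
            voxel_count=len(coords),
        ))
    return stats
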