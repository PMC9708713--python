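"""Trilinear resampling between voxel grids with a shared field-of-view center.

Both grids are interpreted as stacks of voxel centers: voxel ``i`` along an
axis with spacing ``v`` sits at physical offset ``(i - (n - 1) / 2) * v`` from
the field-of-view center.  Resampling maps target voxel centers into source
index space and interpolates with ``scipy.ndimage.map_coordinates`` at order 1
(trilinear), filling outside the source volume with zeros.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def resample_centered(
    values: np.ndarray,
    voxel_size_mm: tuple[float, float, float],
    target_voxel_mm: tuple[float, float, float],
    target_shape: tuple[int, int, int] | None = None,
) -> np.ndarray:
    """Resample ``values`` onto a grid with ``target_voxel_mm`` spacing.

    When ``target_shape`` is omitted it is chosen to cover the source
    field of view (``ceil(n * v / u)`` per axis).  Identity geometry is
    returned unchanged (no interpolation error).
    """
    src_shape = values.shape
    voxel = np.asarray(voxel_size_mm, dtype=float)
    tvox = np.asarray(target_voxel_mm, dtype=float)
    if target_shape is None:
        target_shape = tuple(
            int(np.ceil(n * v / u - 1e-9)) for n, v, u in zip(src_shape, voxel, tvox)
        )
    if tuple(target_shape) == tuple(src_shape) and np.allclose(voxel, tvox):
        return values.copy()
    coords = np.meshgrid(
        *[
            (np.arange(t) - (t - 1) / 2.0) * u / v + (n - 1) / 2.0
            for t, u, v, n in zip(target_shape, tvox, voxel, src_shape)
        ],
        indexing="ij",
    )
    return ndimage.map_coordinates(
        values, np.stack(coords), order=1, mode="constant", cval=0.0
    )
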