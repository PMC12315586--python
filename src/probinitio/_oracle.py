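"""Real-space projection oracle, independent of the Fourier machinery.

Used to validate the projection-slice pathway: this module imports only
numpy and scipy.ndimage and shares no code with the gridding implementation.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def project_oracle(grid: np.ndarray, rot: np.ndarray, shift=(0.0, 0.0)) -> np.ndarray:
    """Project a cubic map along z after rotating the voxel grid.

    The slice-extraction convention samples the volume transform at
    ``rot @ (hx, hy, 0)``; the matching real-space operation resamples the
    volume at ``rot @ x`` (trilinear interpolation about the center voxel
    ``L // 2``), sums along the last axis, then translates the image by
    ``shift`` pixels.
    """
    rot = np.asarray(rot, dtype=float)
    if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-6):
        raise ValueError("rotation must be orthonormal")
    L = grid.shape[0]
    c = L // 2
    center = np.array([c, c, c], dtype=float)
    # affine_transform computes input[R @ out + offset]
    offset = center - rot @ center
    rotated = ndimage.affine_transform(
        grid.astype(np.float64), rot, offset=offset, order=1, mode="constant"
    )
    proj = rotated.sum(axis=2)
    if np.any(np.asarray(shift, dtype=float) != 0):
        proj = ndimage.shift(proj, np.asarray(shift, dtype=float), order=1, mode="constant")
    return proj
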