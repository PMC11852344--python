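"""Low-order spatial polynomial basis shared by the phantom generator and the
background-offset correction."""

from __future__ import annotations

import numpy as np

#: Term order of the 2nd-order basis: 1, x, y, z, x², y², z², xy, xz, yz.
N_TERMS_ORDER2 = 10


def normalized_coords(shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel-index coordinates rescaled to [-1, 1] per axis (degenerate axes → 0)."""
    axes = []
    for n in shape:
        if n > 1:
            axes.append(np.linspace(-1.0, 1.0, n))
        else:
            axes.append(np.zeros(n))
    return tuple(np.meshgrid(*axes, indexing="ij"))


def quadratic_basis(shape: tuple[int, int, int]) -> np.ndarray:
    """Design tensor of the 2nd-order polynomial basis, shape (*shape, 10)."""
    x, y, z = normalized_coords(shape)
    return np.stack(
        [np.ones(shape), x, y, z, x * x, y * y, z * z, x * y, x * z, y * z],
        axis=-1,
    )
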