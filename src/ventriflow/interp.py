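"""Vectorized trilinear sampling of gridded fields at physical positions.

Positions are in mm; voxel (i, j, k) has its center at
``origin + (i + 1/2) * spacing``. Outside the physical box the samplers clamp
to the boundary value; callers that need to detect domain exit test positions
against the box themselves (see :func:`inside_box`).
"""

from __future__ import annotations

import numpy as np


def index_coords(positions: np.ndarray, spacing, origin) -> np.ndarray:
    """Fractional voxel-center coordinates of physical positions (mm)."""
    return (np.asarray(positions, float) - np.asarray(origin, float)) / np.asarray(
        spacing, float
    ) - 0.5


def inside_box(positions: np.ndarray, shape, spacing, origin) -> np.ndarray:
    """Boolean mask of positions strictly inside the grid's physical box."""
    pos = np.asarray(positions, float)
    low = np.asarray(origin, float)
    high = low + np.asarray(shape, float) * np.asarray(spacing, float)
    return np.all((pos >= low) & (pos <= high), axis=-1)


def nearest_voxel(positions: np.ndarray, spacing, origin) -> np.ndarray:
    """Nearest voxel index per position; ties round half-down (lower index)."""
    f = index_coords(positions, spacing, origin)
    return np.ceil(f - 0.5).astype(np.int64)


def trilinear(field: np.ndarray, positions: np.ndarray, spacing, origin) -> np.ndarray:
    """Trilinear interpolation of a scalar or vector field.

    field : (nx, ny, nz) or (nx, ny, nz, C); positions : (N, 3) mm.
    Returns (N,) or (N, C). Coordinates are clamped to the voxel-center hull,
    which extends each boundary value half a voxel outward.
    """
    field = np.asarray(field)
    shape = np.asarray(field.shape[:3])
    f = index_coords(positions, spacing, origin)
    f = np.clip(f, 0.0, shape - 1.0)
    i0 = np.floor(f).astype(np.int64)
    i0 = np.minimum(i0, shape - 2)  # keep an upper neighbour in range
    i0 = np.maximum(i0, 0)
    t = f - i0
    x0, y0, z0 = i0[:, 0], i0[:, 1], i0[:, 2]
    tx, ty, tz = (t[:, k] for k in range(3))
    if field.ndim == 4:
        tx, ty, tz = tx[:, None], ty[:, None], tz[:, None]

    c000 = field[x0, y0, z0]
    c100 = field[x0 + 1, y0, z0]
    c010 = field[x0, y0 + 1, z0]
    c110 = field[x0 + 1, y0 + 1, z0]
    c001 = field[x0, y0, z0 + 1]
    c101 = field[x0 + 1, y0, z0 + 1]
    c011 = field[x0, y0 + 1, z0 + 1]
    c111 = field[x0 + 1, y0 + 1, z0 + 1]

    c00 = c000 * (1 - tx) + c100 * tx
    c10 = c010 * (1 - tx) + c110 * tx
    c01 = c001 * (1 - tx) + c101 * tx
    c11 = c011 * (1 - tx) + c111 * tx
    c0 = c00 * (1 - ty) + c10 * ty
    c1 = c01 * (1 - ty) + c11 * ty
    return c0 * (1 - tz) + c1 * tz


def containing_cell(positions: np.ndarray, shape, spacing, origin) -> np.ndarray:
    """Lower-corner voxel index of the inter-center cell containing each point.

    The cell spans voxel centers ``base .. base + 1`` per axis; points exactly
    on a cell face belong to the lower cell. Clipped so the cell stays in-grid.
    """
    f = index_coords(positions, spacing, origin)
    base = np.ceil(f).astype(np.int64) - 1  # floor, but exact integers drop to k-1
    return np.clip(base, 0, np.asarray(shape, int) - 2)
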