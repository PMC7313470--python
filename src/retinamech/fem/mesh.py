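"""Structured hexahedral meshes on axis-aligned boxes.

The stretcher geometry is a union of axis-aligned boxes, so a tensor-product
grid of 8-node hexahedra is sufficient.  Nodes are numbered with z fastest,
then y, then x; element connectivity follows the VTK_HEXAHEDRON corner
order.  Builders may afterwards drop elements (voids) or duplicate nodes
(unbonded coincident interfaces) by editing the arrays directly.
"""

from __future__ import annotations

import numpy as np

__all__ = ["StructuredHexMesh", "graded_offsets"]


def graded_offsets(length: float, h0: float, hmax: float, ratio: float = 1.35) -> np.ndarray:
    """Monotone cell offsets from 0 to ``length``.

    Cell widths start at ``h0``, grow geometrically by ``ratio`` and are
    capped at ``hmax``; the last cell is stretched/shrunk to land exactly on
    ``length`` (merged with its neighbour when it would be degenerate).
    """
    if not (0 < h0 <= length and hmax > 0 and ratio > 1):
        raise ValueError("invalid grading parameters")
    widths = []
    h, s = h0, 0.0
    while s < length - 1e-15 * length:
        w = min(h, hmax, length - s)
        widths.append(w)
        s += w
        h *= ratio
    if len(widths) > 1 and widths[-1] < 0.4 * widths[-2]:
        widths[-2] += widths[-1]
        widths.pop()
    off = np.concatenate(([0.0], np.cumsum(widths)))
    off[-1] = length
    return off


class StructuredHexMesh:
    """Tensor-product hexahedral mesh from three coordinate vectors."""

    def __init__(self, xs, ys, zs):
        xs = np.asarray(xs, float)
        ys = np.asarray(ys, float)
        zs = np.asarray(zs, float)
        for v in (xs, ys, zs):
            if v.size < 2 or np.any(np.diff(v) <= 0):
                raise ValueError("coordinate vectors must be strictly increasing, length >= 2")
        self.xs, self.ys, self.zs = xs, ys, zs
        nx, ny, nz = xs.size, ys.size, zs.size
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        self.nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

        def nid(i, j, k):
            return (i * ny + j) * nz + k

        i, j, k = np.meshgrid(
            np.arange(nx - 1), np.arange(ny - 1), np.arange(nz - 1), indexing="ij"
        )
        i, j, k = i.ravel(), j.ravel(), k.ravel()
        # VTK hexahedron corner order: bottom quad CCW, then top quad
        self.elems = np.column_stack([
            nid(i, j, k),
            nid(i + 1, j, k),
            nid(i + 1, j + 1, k),
            nid(i, j + 1, k),
            nid(i, j, k + 1),
            nid(i + 1, j, k + 1),
            nid(i + 1, j + 1, k + 1),
            nid(i, j + 1, k + 1),
        ]).astype(np.int64)
        self.cell_ijk = np.column_stack([i, j, k])

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elems(self) -> int:
        return self.elems.shape[0]

    def element_centers(self) -> np.ndarray:
        return self.nodes[self.elems].mean(axis=1)

    def element_sizes(self) -> np.ndarray:
        """(E, 3) edge lengths hx, hy, hz of each (axis-aligned) element."""
        p = self.nodes[self.elems]
        return np.column_stack([
            p[:, 1, 0] - p[:, 0, 0],
            p[:, 3, 1] - p[:, 0, 1],
            p[:, 4, 2] - p[:, 0, 2],
        ])
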