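"""Structured quadrilateral meshes for the mixed velocity-pressure pair.

Every element carries 9 velocity nodes (biquadratic, tensor ordering
``local = 3*j + i`` over the reference square) and reuses its 4 corner
nodes for the bilinear pressure space. Pressure unknowns live on the
subset of vertex nodes; ``pressure_map`` sends a global node id to its
pressure dof (or -1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import MeshError

__all__ = ["Mesh2D", "rect_mesh"]

#: Local velocity-node indices that are element corners (pressure nodes).
CORNER_LOCALS = (0, 2, 6, 8)


@dataclass
class Mesh2D:
    """A 2-D mesh of 9-node quadrilaterals with a bilinear pressure subset."""

    node_coords: np.ndarray  # (n_nodes, 2), metres
    elements: np.ndarray  # (n_elem, 9) velocity connectivity
    boundary_tags: dict[str, np.ndarray]  # tag -> sorted node ids
    pressure_map: np.ndarray = field(default=None)  # node id -> pressure dof or -1

    def __post_init__(self) -> None:
        self.node_coords = np.asarray(self.node_coords, float)
        self.elements = np.asarray(self.elements, int)
        if self.elements.shape[1] != 9:
            raise MeshError("elements must have 9 velocity nodes each")
        if self.pressure_map is None:
            pnodes = np.unique(self.elements[:, list(CORNER_LOCALS)])
            pmap = np.full(self.n_nodes, -1, dtype=int)
            pmap[pnodes] = np.arange(pnodes.size)
            self.pressure_map = pmap

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def n_pressure(self) -> int:
        return int((self.pressure_map >= 0).sum())

    def pressure_elements(self) -> np.ndarray:
        """(n_elem, 4) pressure-dof connectivity (corner nodes)."""
        corners = self.elements[:, list(CORNER_LOCALS)]
        return self.pressure_map[corners]

    def boundary_nodes(self, tag: str) -> np.ndarray:
        if tag not in self.boundary_tags:
            raise KeyError(
                f"unknown boundary tag '{tag}'; have {sorted(self.boundary_tags)}"
            )
        return self.boundary_tags[tag]

    def all_boundary_nodes(self) -> np.ndarray:
        return np.unique(np.concatenate(list(self.boundary_tags.values())))

    def save_txt(self, path) -> None:
        """Plain-text export: node block then element block."""
        with open(path, "w") as fh:
            fh.write(f"# myoloop fe mesh: {self.n_nodes} nodes, {self.n_elements} elements\n")
            fh.write("nodes\n")
            for i, (x, y) in enumerate(self.node_coords):
                fh.write(f"{i} {x:.16g} {y:.16g}\n")
            fh.write("elements\n")
            for e, conn in enumerate(self.elements):
                fh.write(f"{e} " + " ".join(map(str, conn)) + "\n")


def rect_mesh(
    nx: int,
    ny: int,
    lx: float = 1.0,
    ly: float = 1.0,
    distortion: float = 0.0,
) -> Mesh2D:
    """Structured nx-by-ny element mesh of the rectangle [0,lx] x [0,ly].

    ``distortion`` applies a fixed smooth interior remap
    ``x += a*sin(pi x/lx)*sin(pi y/ly)`` (same for y) that vanishes on
    the boundary: the domain is unchanged but mesh lines curve, which is
    useful to make polynomial exact solutions non-trivial in convergence
    studies. Boundary tags: left, right, bottom, top (corners belong to
    both adjacent tags).
    """
    if nx < 1 or ny < 1:
        raise MeshError("need at least one element per direction")
    w, h = 2 * nx + 1, 2 * ny + 1
    xs = np.linspace(0.0, lx, w)
    ys = np.linspace(0.0, ly, h)
    xg, yg = np.meshgrid(xs, ys, indexing="xy")
    coords = np.column_stack([xg.ravel(), yg.ravel()])

    if distortion:
        sx = np.sin(np.pi * coords[:, 0] / lx) * np.sin(np.pi * coords[:, 1] / ly)
        coords = coords + distortion * np.column_stack([lx * sx, ly * sx])

    def nid(ix, iy):
        return iy * w + ix

    elements = np.empty((nx * ny, 9), dtype=int)
    e = 0
    for ey in range(ny):
        for ex in range(nx):
            ix, iy = 2 * ex, 2 * ey
            elements[e] = [nid(ix + i, iy + j) for j in range(3) for i in range(3)]
            e += 1

    ix_all = np.arange(w * h) % w
    iy_all = np.arange(w * h) // w
    tags = {
        "left": np.flatnonzero(ix_all == 0),
        "right": np.flatnonzero(ix_all == w - 1),
        "bottom": np.flatnonzero(iy_all == 0),
        "top": np.flatnonzero(iy_all == h - 1),
    }
    return Mesh2D(node_coords=coords, elements=elements, boundary_tags=tags)
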