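"""Forward finite-element model of the two-scaffold tissue stretcher.

Geometry (experimental-device defaults): two stiff titanium scaffolds, each
3 mm x 10 mm x 0.1 mm, lie side by side in the x-y plane; the soft,
near-incompressible retina (6 mm x 10 mm x 0.22 mm, nu = 0.49) is bonded on
top, covering both.  One scaffold is clamped in all directions, the other is
constrained to in-plane motion (u_z = 0) and carries a uniform x-traction on
its outer sidewall.  The model returns the loaded scaffold's mean sidewall
x-displacement u_x, whose ratio to the applied load is the structural
stiffness measured in the stretching experiments.

With zero initial gap the two scaffolds touch but are *not* bonded: the
coincident interface nodes are duplicated so the plates interact only
through the retina.  The retina keeps its own nodes along the interface
line, bonded to each scaffold's top face strictly on that scaffold's side.
The mesh is graded toward the interface, where the deformation (a shear
band in the retina above the gap) localises.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .elasticity import assemble_stiffness, face_loads, solve_displacement, strain_energy
from .mesh import StructuredHexMesh, graded_offsets

__all__ = [
    "StretcherConfig",
    "FEModel",
    "FESolution",
    "StretcherModel",
    "build_model",
    "solve_forward",
    "effective_stiffness",
    "export_vtu",
]

REGION_FIXED, REGION_MOVING, REGION_RETINA = 0, 1, 2


@dataclass(frozen=True)
class StretcherConfig:
    """Geometry, materials and load of the stretcher model (SI units).

    Defaults reproduce the experimental device: titanium scaffolds
    (E = 105 GPa, nu = 0.33 -- standard values; the precise numbers are
    immaterial because the scaffolds are ~1e8 times stiffer than the
    retina), retina density 1017 kg/m^3 (carried for fidelity; the static
    solve has no body force) and a 1.0 mN total sidewall load.
    """

    scaffold_width: float = 3.0e-3
    depth: float = 10.0e-3
    scaffold_height: float = 0.1e-3
    retina_width: float = 6.0e-3
    retina_height: float = 0.22e-3
    E_scaffold: float = 105e9
    nu_scaffold: float = 0.33
    E_retina: float = 760.0
    nu_retina: float = 0.49
    rho_retina: float = 1017.0
    load: float = 1.0e-3
    gap: float = 0.0

    def __post_init__(self):
        for name in ("scaffold_width", "depth", "scaffold_height",
                     "retina_width", "retina_height", "E_scaffold", "E_retina"):
            if not getattr(self, name) > 0:
                raise ValueError(f"StretcherConfig.{name} must be positive")
        if not 0 < self.nu_retina < 0.5:
            raise ValueError("retina Poisson ratio must lie in (0, 0.5)")
        if not -1 < self.nu_scaffold < 0.5:
            raise ValueError("scaffold Poisson ratio out of range")
        if self.gap < 0:
            raise ValueError("gap must be non-negative")
        expected = 2 * self.scaffold_width + self.gap
        if abs(self.retina_width - expected) > 1e-9:
            raise ValueError(
                f"retina width {self.retina_width} must equal "
                f"2 * scaffold width + gap = {expected}"
            )
        if self.E_scaffold / self.E_retina < 1e4:
            warnings.warn(
                "scaffold/retina stiffness ratio < 1e4; the rigid-scaffold "
                "assumption behind the readout may be inaccurate",
                stacklevel=2,
            )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StretcherConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class FEModel:
    """Discretised stretcher: mesh, region tags, constraints and load faces."""

    nodes: np.ndarray
    elems: np.ndarray
    region: np.ndarray            # per-element region code
    clamped_nodes: np.ndarray     # fixed scaffold: all dofs zero
    inplane_nodes: np.ndarray     # moving scaffold: u_z = 0
    loaded_faces: np.ndarray      # (F, 4) quads on the moving scaffold sidewall
    resolution: int
    config: StretcherConfig

    @property
    def dof_count(self) -> int:
        return 3 * self.nodes.shape[0]

    @property
    def loaded_area(self) -> float:
        p = self.nodes[self.loaded_faces]
        return float(np.sum(np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 3] - p[:, 0]), axis=1)))

    def dirichlet_mask(self) -> np.ndarray:
        mask = np.zeros(self.dof_count, bool)
        for nid in self.clamped_nodes:
            mask[3 * nid: 3 * nid + 3] = True
        mask[3 * self.inplane_nodes + 2] = True
        return mask


@dataclass(frozen=True)
class FESolution:
    """Displacement field and scalar readout of one forward solve."""

    u: np.ndarray           # (N, 3) nodal displacements [m]
    u_x: float              # mean x-displacement of the loaded sidewall [m]
    residual: float
    E_retina: float
    load: float
    energy: float           # stored strain energy [J]

    def __post_init__(self):
        if self.load > 0 and not self.u_x > 0:
            raise RuntimeError("positive load produced non-positive sidewall displacement")


def _mesh_counts(resolution: int) -> dict:
    if resolution < 1:
        raise ValueError("resolution must be a positive integer")
    return {
        "nz_scaffold": 2,
        "nz_retina": 3 * resolution,
        "ny": 6 * resolution,
        "hmax": 2.4e-3 / resolution,
    }


def build_model(config: StretcherConfig, resolution: int = 4) -> FEModel:
    """Structured hexahedral mesh of the stretcher with region/face tags."""
    c = _mesh_counts(resolution)
    w, g = config.scaffold_width, config.gap
    h_s, h_r = config.scaffold_height, config.retina_height
    if c["nz_retina"] < 2:
        raise ValueError("resolution too coarse: need >= 2 elements through the retina")

    h0 = h_r / c["nz_retina"]
    half = graded_offsets(w, h0, c["hmax"])
    xs_left = w - half[::-1]
    xs_right = (w + g) + half
    if g > 0:
        n_gap = min(4, max(1, int(round(g / h0))))
        xs_gap = w + np.linspace(0.0, g, n_gap + 1)[1:-1]
        xs = np.concatenate([xs_left, xs_gap, xs_right])
    else:
        xs = np.concatenate([xs_left, xs_right[1:]])
    ys = np.linspace(0.0, config.depth, c["ny"] + 1)
    zs = np.concatenate([
        np.linspace(0.0, h_s, c["nz_scaffold"] + 1),
        np.linspace(h_s, h_s + h_r, c["nz_retina"] + 1)[1:],
    ])

    mesh = StructuredHexMesh(xs, ys, zs)
    nodes = mesh.nodes.copy()
    elems = mesh.elems.copy()
    centers = mesh.element_centers()

    in_scaffold_layer = centers[:, 2] < h_s
    region = np.full(mesh.n_elems, REGION_RETINA, dtype=np.int8)
    region[in_scaffold_layer & (centers[:, 0] < w)] = REGION_FIXED
    region[in_scaffold_layer & (centers[:, 0] > w + g)] = REGION_MOVING
    void = in_scaffold_layer & (centers[:, 0] >= w) & (centers[:, 0] <= w + g)

    if void.any():
        elems = elems[~void]
        region = region[~void]

    if g == 0:
        # unbond the coincident scaffold-scaffold interface: the moving
        # scaffold and the retina each get their own copies of the interface
        # nodes so the plates couple only through the retina.
        tol = 1e-12
        iface = np.flatnonzero(
            (np.abs(nodes[:, 0] - w) < tol) & (nodes[:, 2] <= h_s + tol)
        )
        for reg in (REGION_MOVING, REGION_RETINA):
            sel = region == reg
            used = np.isin(elems[sel], iface)
            dup_ids = np.unique(elems[sel][used])
            if dup_ids.size == 0:
                continue
            new_ids = np.arange(nodes.shape[0], nodes.shape[0] + dup_ids.size)
            nodes = np.vstack([nodes, nodes[dup_ids]])
            remap = dict(zip(dup_ids.tolist(), new_ids.tolist()))
            block = elems[sel]
            flat = block.ravel()
            hit = np.isin(flat, dup_ids)
            flat[hit] = np.vectorize(remap.__getitem__)(flat[hit])
            elems[sel] = flat.reshape(block.shape)

    # drop nodes no element references (void region, superseded originals)
    used = np.unique(elems)
    remap = np.full(nodes.shape[0], -1, dtype=np.int64)
    remap[used] = np.arange(used.size)
    nodes = nodes[used]
    elems = remap[elems]

    clamped = np.unique(elems[region == REGION_FIXED])
    moving_nodes = np.unique(elems[region == REGION_MOVING])

    xmax = xs[-1]
    moving = elems[region == REGION_MOVING]
    on_outer = np.abs(nodes[moving[:, 1], 0] - xmax) < 1e-12
    loaded_faces = moving[on_outer][:, [1, 2, 6, 5]]
    if loaded_faces.size == 0:
        raise ValueError("no loaded sidewall faces found; mesh construction failed")

    return FEModel(
        nodes=nodes,
        elems=elems,
        region=region,
        clamped_nodes=clamped,
        inplane_nodes=moving_nodes,
        loaded_faces=loaded_faces,
        resolution=resolution,
        config=config,
    )


class StretcherModel:
    """Forward elasticity model of the stretcher, reusable across moduli.

    The stiffness matrix splits as ``K = K_scaffold + E_retina * K_unit``
    (retina stiffness is linear in its modulus), so repeated solves during
    the inverse identification reassemble cheaply.
    """

    def __init__(self, config: StretcherConfig | None = None, resolution: int = 4):
        self.config = config or StretcherConfig()
        self.model = build_model(self.config, resolution)
        m = self.model
        scaffold = m.region != REGION_RETINA
        self._K_scaffold = assemble_stiffness(
            m.nodes, m.elems[scaffold],
            self.config.E_scaffold, self.config.nu_scaffold,
        )
        self._K_retina_unit = assemble_stiffness(
            m.nodes, m.elems[~scaffold], 1.0, self.config.nu_retina,
        )
        self._fixed = m.dirichlet_mask()
        traction = np.array([1.0, 0.0, 0.0]) / m.loaded_area
        self._f_unit = face_loads(m.nodes, m.loaded_faces, traction, ndof=m.dof_count)
        self._loaded_nodes = np.unique(m.loaded_faces)

    @property
    def dof_count(self) -> int:
        return self.model.dof_count

    def solve(self, E_retina: float | None = None, load: float | None = None) -> FESolution:
        """Static solve at retinal modulus ``E_retina`` under total load ``load``."""
        E = self.config.E_retina if E_retina is None else float(E_retina)
        P = self.config.load if load is None else float(load)
        if not E > 0:
            raise ValueError("retinal modulus must be positive")
        K = self._K_scaffold + E * self._K_retina_unit
        f = P * self._f_unit
        uvec, info = solve_displacement(K, f, self._fixed)
        u = uvec.reshape(-1, 3)
        u_x = float(u[self._loaded_nodes, 0].mean())
        return FESolution(
            u=u, u_x=u_x, residual=info["residual"],
            E_retina=E, load=P, energy=strain_energy(K, uvec),
        )

    def effective_stiffness(self, E_retina: float | None = None) -> float:
        """Structural stiffness load / u_x [N/m] at the given modulus."""
        sol = self.solve(E_retina=E_retina)
        if sol.u_x == 0:
            raise ZeroDivisionError("zero sidewall displacement; stiffness undefined")
        return sol.load / sol.u_x

    def export_vtu(self, path: str | Path, solution: FESolution | None = None) -> None:
        point_data = {}
        if solution is not None:
            point_data["displacement"] = solution.u
        export_vtu(path, self.model.nodes, self.model.elems, point_data,
                   cell_data={"region": self.model.region})


def solve_forward(model: StretcherModel, config: StretcherConfig | None = None) -> FESolution:
    """Functional wrapper around :meth:`StretcherModel.solve`."""
    if config is not None:
        return model.solve(E_retina=config.E_retina, load=config.load)
    return model.solve()


def effective_stiffness(model: StretcherModel, config: StretcherConfig | None = None) -> float:
    E = None if config is None else config.E_retina
    return model.effective_stiffness(E_retina=E)


def export_vtu(path: str | Path, nodes, elems, point_data=None, cell_data=None) -> None:
    """Minimal ASCII VTU (unstructured-grid) writer for hexahedral meshes."""
    nodes = np.asarray(nodes, float)
    elems = np.asarray(elems)
    n_pts, n_cells = nodes.shape[0], elems.shape[0]
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cells}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        "\n".join(" ".join(f"{v:.9e}" for v in row) for row in nodes),
        "</DataArray>", "</Points>",
    ]
    if point_data:
        lines.append("<PointData>")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            lines.append(
                f'<DataArray type="Float64" Name="{name}" '
                f'NumberOfComponents="{ncomp}" format="ascii">'
            )
            lines.append("\n".join(
                " ".join(f"{v:.9e}" for v in np.atleast_1d(row)) for row in arr
            ))
            lines.append("</DataArray>")
        lines.append("</PointData>")
    if cell_data:
        lines.append("<CellData>")
        for name, arr in cell_data.items():
            lines.append(f'<DataArray type="Int32" Name="{name}" format="ascii">')
            lines.append(" ".join(str(int(v)) for v in arr))
            lines.append("</DataArray>")
        lines.append("</CellData>")
    lines += [
        "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        "\n".join(" ".join(str(i) for i in row) for row in elems),
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        " ".join(str(8 * (i + 1)) for i in range(n_cells)),
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        " ".join("12" for _ in range(n_cells)),
        "</DataArray>",
        "</Cells>", "</Piece>", "</UnstructuredGrid>", "</VTKFile>",
    ]
    Path(path).write_text("\n".join(lines))
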