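"""FE core: benchmarks with closed forms, stretcher invariants, I/O."""

import xml.etree.ElementTree as ET

import numpy as np
import pytest

from retinamech.fem.elasticity import (
    assemble_stiffness,
    face_loads,
    solve_displacement,
    strain_energy,
)
from retinamech.fem.mesh import StructuredHexMesh, graded_offsets
from retinamech.fem.stretcher import (
    StretcherConfig,
    StretcherModel,
    build_model,
    export_vtu,
)


def _block_patch(E, nu, nx=5, ny=4, nz=4):
    """Uniaxial tension of a block with roller + pin constraints.

    The back face rides on rollers (u_x = 0) and rigid-body modes are pinned
    at single nodes, so the exact solution is a uniform stress state that
    trilinear elements must reproduce to machine precision.
    """
    L, W, H = 2e-3, 1e-3, 1e-3
    mesh = StructuredHexMesh(np.linspace(0, L, nx), np.linspace(0, W, ny),
                             np.linspace(0, H, nz))
    K = assemble_stiffness(mesh.nodes, mesh.elems, E, nu)
    sel = np.abs(mesh.nodes[mesh.elems[:, 1], 0] - L) < 1e-15
    F_total = 1e-3
    f = face_loads(mesh.nodes, mesh.elems[sel][:, [1, 2, 6, 5]],
                   np.array([F_total / (W * H), 0, 0]))
    fixed = np.zeros(3 * mesh.n_nodes, bool)
    back = np.flatnonzero(np.abs(mesh.nodes[:, 0]) < 1e-15)
    fixed[3 * back] = True

    def nid(pt):
        return int(np.argmin(np.linalg.norm(mesh.nodes - np.asarray(pt), axis=1)))

    origin, along_y = nid((0, 0, 0)), nid((0, W, 0))
    fixed[3 * origin + 1] = fixed[3 * origin + 2] = True
    fixed[3 * along_y + 2] = True
    u, info = solve_displacement(K, f, fixed)
    end = np.flatnonzero(np.abs(mesh.nodes[:, 0] - L) < 1e-15)
    u_end = u.reshape(-1, 3)[end, 0].mean()
    return u_end, F_total * L / (E * W * H), K, u, f


class TestElementBenchmarks:
    @pytest.mark.parametrize("nu", [0.3, 0.49])
    def test_uniaxial_patch_test_exact(self, nu):
        u_end, exact, *_ = _block_patch(E=1000.0, nu=nu)
        assert u_end == pytest.approx(exact, rel=1e-6)

    def test_external_work_equals_strain_energy(self):
        _, _, K, u, f = _block_patch(E=1000.0, nu=0.49)
        assert strain_energy(K, u) == pytest.approx(0.5 * f @ u, rel=1e-10)

    def test_simple_shear_of_thin_bonded_layer(self):
        # soft layer between a clamped base and a tangentially moved rigid
        # plate: F = G*A*delta/t, with >= 4 elements through the thickness
        L, t = 4e-3, 0.05e-3
        E, nu = 1000.0, 0.49
        G = E / (2 * (1 + nu))
        mesh = StructuredHexMesh(np.linspace(0, L, 33), np.linspace(0, L, 9),
                                 np.linspace(0, t, 5))
        K = assemble_stiffness(mesh.nodes, mesh.elems, E, nu)
        ndof = 3 * mesh.n_nodes
        fixed = np.zeros(ndof, bool)
        vals = np.zeros(ndof)
        bottom = np.flatnonzero(np.abs(mesh.nodes[:, 2]) < 1e-15)
        top = np.flatnonzero(np.abs(mesh.nodes[:, 2] - t) < 1e-15)
        for n in bottom:
            fixed[3 * n: 3 * n + 3] = True
        delta = 1e-6
        fixed[3 * top] = True
        vals[3 * top] = delta
        fixed[3 * top + 2] = True
        u, info = solve_displacement(K, np.zeros(ndof), fixed, vals[fixed])
        constrained = np.flatnonzero(fixed)
        F = info["reactions"][np.isin(constrained, 3 * top)].sum()
        assert F == pytest.approx(G * L * L * delta / t, rel=0.02)

    def test_volumetric_locking_is_mitigated(self):
        # near-incompressible shear answer must not degrade vs nu = 0.3
        u49, exact49, *_ = _block_patch(E=1000.0, nu=0.499)
        assert u49 == pytest.approx(exact49, rel=1e-6)


class TestStretcherModel:
    def test_zero_load_gives_zero_field(self, stretcher_res1):
        sol = stretcher_res1.solve(load=0.0)
        assert np.max(np.abs(sol.u)) == 0.0

    def test_displacement_linear_in_load(self, stretcher_res1):
        a = stretcher_res1.solve(load=1e-3)
        b = stretcher_res1.solve(load=2e-3)
        assert b.u_x == pytest.approx(2 * a.u_x, rel=1e-9)

    def test_modulus_displacement_product_constant(self, stretcher_res1):
        # soft retina dominates: E * u_x constant to < 0.5% across 100-5000 Pa
        prods = [E * stretcher_res1.solve(E_retina=E).u_x for E in (100.0, 760.0, 5000.0)]
        assert (max(prods) - min(prods)) / min(prods) < 0.005

    def test_loaded_sidewall_uniform_along_depth(self, stretcher_res1):
        # geometry and load are y-uniform; u_x across the sidewall < 1% spread
        sol = stretcher_res1.solve()
        m = stretcher_res1.model
        nodes = np.unique(m.loaded_faces)
        ux = sol.u[nodes, 0]
        assert (ux.max() - ux.min()) / ux.mean() < 0.01

    def test_work_energy_consistency(self, stretcher_res1):
        sol = stretcher_res1.solve()
        assert sol.energy == pytest.approx(0.5 * sol.load * sol.u_x, rel=0.02)

    def test_effective_stiffness_scales_with_modulus(self, stretcher_res1):
        k1 = stretcher_res1.effective_stiffness(E_retina=500.0)
        k2 = stretcher_res1.effective_stiffness(E_retina=1000.0)
        assert k2 == pytest.approx(2 * k1, rel=0.005)

    def test_mesh_converges_with_open_gap(self):
        # with a finite scaffold separation the boundary data are regular and
        # the sidewall displacement converges under refinement
        cfg = StretcherConfig(gap=0.2e-3, retina_width=6.2e-3)
        u = [StretcherModel(cfg, resolution=r).solve().u_x for r in (1, 2, 4)]
        assert abs(u[2] - u[1]) / u[2] < 0.03

    def test_solver_residual_is_small(self, stretcher_res2):
        assert stretcher_res2.solve().residual < 1e-4


class TestModelConstruction:
    def test_interface_nodes_are_duplicated_not_shared(self, stretcher_res1):
        m = stretcher_res1.model
        w = m.config.scaffold_width
        h = m.config.scaffold_height
        on_line = (np.abs(m.nodes[:, 0] - w) < 1e-12) & (m.nodes[:, 2] <= h + 1e-12)
        coords = m.nodes[on_line]
        # every interface location appears at least twice (scaffold-scaffold
        # and scaffold-retina unbonding)
        uniq, counts = np.unique(np.round(coords, 12), axis=0, return_counts=True)
        assert np.all(counts >= 2)
        fixed_set = set(m.elems[m.region == 0].ravel())
        moving_set = set(m.elems[m.region == 1].ravel())
        assert not fixed_set & moving_set

    def test_medium_resolution_dof_count_in_expected_range(self):
        model = build_model(StretcherConfig(), resolution=6)
        assert 5e4 <= model.dof_count <= 3e5

    def test_invalid_configurations_rejected(self):
        with pytest.raises(ValueError):
            StretcherConfig(retina_width=5e-3)  # != 2*scaffold + gap
        with pytest.raises(ValueError):
            StretcherConfig(nu_retina=0.5)
        with pytest.raises(ValueError):
            build_model(StretcherConfig(), resolution=0)

    def test_soft_scaffold_warns(self):
        with pytest.warns(UserWarning):
            StretcherConfig(E_scaffold=1e6)

    def test_graded_offsets_cover_interval(self):
        off = graded_offsets(3e-3, 0.05e-3, 0.5e-3)
        assert off[0] == 0.0 and off[-1] == 3e-3
        assert np.all(np.diff(off) > 0)

    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = StretcherConfig(E_retina=1234.0)
        cfg.to_yaml(tmp_path / "c.yaml")
        assert StretcherConfig.from_yaml(tmp_path / "c.yaml") == cfg

    def test_vtu_export_is_wellformed(self, tmp_path, stretcher_res1):
        sol = stretcher_res1.solve()
        path = tmp_path / "field.vtu"
        stretcher_res1.export_vtu(path, sol)
        root = ET.parse(path).getroot()
        piece = root.find(".//Piece")
        assert int(piece.get("NumberOfPoints")) == stretcher_res1.model.nodes.shape[0]
        assert int(piece.get("NumberOfCells")) == stretcher_res1.model.elems.shape[0]
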