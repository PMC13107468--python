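"""Geometry I/O, canonical orientation and dimer/grid construction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pistack.fixtures import fixture
from pistack.geometry import (GeometryError, Molecule, PlanarityError, ScanGrid,
                              XYZParseError, build_dimer, canonical_orient,
                              make_grid, parse_xyz, read_xyz, write_xyz)


class TestXYZ:
    def test_fixture_round_trip(self, tmp_path):
        mol = fixture("benzene").molecule
        path = tmp_path / "benzene.xyz"
        write_xyz(mol, path, comment="test")
        back = read_xyz(path)
        assert back.natom == 12
        assert back.formula == "C6H6"
        np.testing.assert_allclose(back.coords, mol.coords, atol=1e-9)

    def test_minimal_single_atom(self):
        mol = parse_xyz("1\n\nHe 0 0 0\n")
        assert mol.natom == 1
        assert mol.elements == ("He",)
        np.testing.assert_allclose(mol.coords, 0.0)

    def test_declared_count_mismatch(self):
        text = "5\ncomment\n" + "H 0 0 0\n" * 4
        with pytest.raises(XYZParseError, match="5 atoms"):
            parse_xyz(text)

    def test_malformed_coordinate_line(self):
        with pytest.raises(XYZParseError, match="line 3"):
            parse_xyz("1\n\nH zero 0 0\n")

    def test_unknown_element(self):
        with pytest.raises(GeometryError, match="Xx"):
            parse_xyz("1\n\nXx 0 0 0\n")


class TestCanonicalOrient:
    def test_idempotent(self):
        mol = fixture("pentacene").molecule
        again = canonical_orient(mol)
        assert np.abs(again.coords - mol.coords).max() < 1e-10

    def test_rotated_benzene_inertia_diagonal(self):
        """Re-orientation must diagonalize the inertia tensor; verified
        against an independently coded moment-of-inertia calculation."""
        rng = np.random.default_rng(7)
        mol = fixture("benzene").molecule
        # random rotation
        A = rng.standard_normal((3, 3))
        Q, _ = np.linalg.qr(A)
        if np.linalg.det(Q) < 0:
            Q[:, 0] = -Q[:, 0]
        rotated = Molecule(mol.elements, mol.coords @ Q.T)
        out = canonical_orient(rotated)

        # independent oracle: inertia tensor with unit masses
        c = out.coords - out.coords.mean(axis=0)
        r2 = (c ** 2).sum(axis=1)
        inertia = np.diag(r2.sum() * np.ones(3)) - c.T @ c
        off = inertia - np.diag(np.diag(inertia))
        assert np.abs(off).max() < 1e-8

    def test_nonplanar_rejected(self):
        # pyramidalized ammonia-like geometry
        mol = Molecule(
            ("N", "H", "H", "H"),
            np.array([
                (0.0, 0.0, 0.38),
                (0.94, 0.0, -0.13),
                (-0.47, 0.81, -0.13),
                (-0.47, -0.81, -0.13),
            ]),
        )
        with pytest.raises(PlanarityError) as exc:
            canonical_orient(mol)
        assert exc.value.max_dev > 1e-3

    def test_long_axis_on_x(self):
        mol = fixture("naphthalene").molecule
        spans = mol.coords.max(axis=0) - mol.coords.min(axis=0)
        assert spans[0] > spans[1] > spans[2]
        assert mol.max_out_of_plane() < 1e-10


class TestBuildDimer:
    def test_cofacial_definition(self):
        mol = fixture("benzene").molecule
        dim = build_dimer(mol, 0.0, 0.0, 3.4)
        diff = dim.mobile.coords - dim.fixed.coords
        np.testing.assert_allclose(diff[:, :2], 0.0, atol=1e-14)
        np.testing.assert_allclose(diff[:, 2], 3.4)

    def test_translation_additivity(self):
        mol = fixture("benzene").molecule
        d1 = build_dimer(mol, 1.0, 0.5, 3.4)
        shifted = d1.mobile.translated((0.3, 0.2, 0.0))
        d2 = build_dimer(mol, 1.3, 0.7, 3.4)
        np.testing.assert_allclose(shifted.coords, d2.mobile.coords, atol=1e-12)

    def test_negative_shift_symmetry_equivalent(self):
        """-dx and +dx arrangements are related by the monomer's C2 rotation
        about z (x,y -> -x,-y): same interatomic distance multiset."""
        mol = fixture("naphthalene").molecule
        dp = build_dimer(mol, 1.0, 0.0, 3.4)
        dm = build_dimer(mol, -1.0, 0.0, 3.4)

        def distances(dim):
            d = dim.fixed.coords[:, None, :] - dim.mobile.coords[None, :, :]
            return np.sort(np.linalg.norm(d, axis=2).ravel())

        np.testing.assert_allclose(distances(dp), distances(dm), atol=1e-9)

    def test_intramonomer_distances_conserved(self):
        mol = fixture("anthracene").molecule
        dim = build_dimer(mol, 2.0, 1.0, 3.4)
        da = np.linalg.norm(
            mol.coords[:, None] - mol.coords[None, :], axis=2)
        db = np.linalg.norm(
            dim.mobile.coords[:, None] - dim.mobile.coords[None, :], axis=2)
        np.testing.assert_allclose(da, db, atol=1e-12)

    def test_nonpositive_dz_rejected(self):
        mol = fixture("benzene").molecule
        with pytest.raises(GeometryError):
            build_dimer(mol, 0.0, 0.0, 0.0)
        with pytest.raises(GeometryError):
            build_dimer(mol, 0.0, 0.0, -1.0)


class TestScanGrid:
    def test_standard_grid_count(self):
        grid = ScanGrid(axis="x", start=0.0, stop=14.0, step=0.1, dz=3.4)
        mol = fixture("benzene").molecule
        arrs = make_grid(mol, grid)
        assert len(arrs) == 141
        assert arrs[0].dx == 0.0
        assert abs(arrs[-1].dx - 14.0) < 1e-9

    def test_fixed_dy_cut(self):
        grid = ScanGrid(axis="x_at_fixed_y", start=0.0, stop=2.0, step=0.5,
                        dz=3.4, fixed_dy=1.0)
        arrs = make_grid(fixture("benzene").molecule, grid)
        assert all(a.dy == 1.0 for a in arrs)

    def test_degenerate_single_point(self):
        grid = ScanGrid(axis="y", start=1.5, stop=1.5, step=0.1, dz=3.4)
        arrs = make_grid(fixture("benzene").molecule, grid)
        assert len(arrs) == 1
        assert arrs[0].dy == 1.5

    def test_invalid_grids_rejected(self):
        with pytest.raises(GeometryError):
            ScanGrid(axis="x", start=0, stop=1, step=-0.1)
        with pytest.raises(GeometryError):
            ScanGrid(axis="x", start=2, stop=1, step=0.1)
        with pytest.raises(GeometryError):
            ScanGrid(axis="x_at_fixed_y", start=0, stop=1, step=0.1)
        with pytest.raises(GeometryError):
            ScanGrid(axis="x", start=0, stop=1, step=0.1, fixed_dy=1.0)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(start=st.floats(0, 5), n=st.integers(1, 60),
           step=st.sampled_from([0.05, 0.1, 0.2, 0.25]))
    def test_grid_point_arithmetic(self, start, n, step):
        stop = start + n * step
        grid = ScanGrid(axis="x", start=start, stop=stop, step=step, dz=3.4)
        pts = grid.points
        assert len(pts) == n + 1
        np.testing.assert_allclose(np.diff(pts), step, atol=1e-9)


class TestMoleculeInvariants:
    def test_electron_and_formula_bookkeeping(self):
        mol = fixture("pentacene").molecule
        assert mol.formula == "C22H14"
        assert mol.n_electrons == 22 * 6 + 14

    def test_open_shell_rejected(self):
        with pytest.raises(GeometryError):
            Molecule(("H",), np.zeros((1, 3)), spin_multiplicity=2)

    def test_nonfinite_coords_rejected(self):
        with pytest.raises(GeometryError):
            Molecule(("H",), np.array([[np.nan, 0, 0]]))
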