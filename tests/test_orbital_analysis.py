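"""pi/sigma classification, parities, phases, cross overlaps, pair counts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pistack import integrals
from pistack.estruct import dimer_basis, embed_coefficients
from pistack.fixtures import fixture
from pistack.geometry import PlanarityError
from pistack.mopce import MopceContext, squared_overlap_sums
from pistack.orbital_analysis import (classify_orbitals, count_pairs,
                                      cross_overlap, fix_phases)
from pistack.scf import run_rhf


class TestClassification:
    def test_ethylene_single_pi(self, ethylene_labels):
        assert len(ethylene_labels.pi_indices) == 1
        assert len(ethylene_labels.sigma_indices) == 7

    def test_benzene_pi_count(self, benzene_labels):
        """3 doubly occupied pi MOs (6 pi electrons), 18 sigma."""
        assert len(benzene_labels.pi_indices) == 3
        assert len(benzene_labels.sigma_indices) == 18
        # degenerate e-set splits into one S and one A component
        assert len(benzene_labels.pi_by_parity("S")) == 2
        assert len(benzene_labels.pi_by_parity("A")) == 1

    def test_pi_count_is_half_pi_electrons(self, benzene_labels):
        # 6 conjugated pi electrons -> 3 doubly occupied pi orbitals
        assert len(benzene_labels.pi_indices) == 6 // 2

    def test_classification_stable_under_basis(self):
        mol = fixture("benzene").molecule
        for basis in ("sto-3g", "3-21g", "6-31g"):
            lab = classify_orbitals(run_rhf(mol, basis))
            assert len(lab.pi_indices) == 3
            assert len(lab.pi_by_parity("S")) == 2

    def test_ranks_are_gapless_and_energy_ordered(self, benzene_labels):
        for parity in ("S", "A"):
            idx = benzene_labels.pi_by_parity(parity)
            ranks = [benzene_labels.labels[i].class_rank for i in idx]
            energies = [benzene_labels.labels[i].energy for i in idx]
            assert ranks == list(range(1, len(idx) + 1))
            assert energies == sorted(energies)

    def test_nonplanar_rejected(self):
        from pistack.geometry import Molecule

        mol = Molecule(
            ("N", "H", "H", "H"),
            np.array([(0.0, 0.0, 0.38), (0.94, 0.0, -0.13),
                      (-0.47, 0.81, -0.13), (-0.47, -0.81, -0.13)]),
        )
        scf = run_rhf(mol, "sto-3g")
        with pytest.raises(PlanarityError):
            classify_orbitals(scf)

    def test_csv_export(self, benzene_labels, tmp_path):
        path = tmp_path / "cls.csv"
        benzene_labels.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert set(df.columns) >= {"index", "energy_hartree", "class",
                                   "parity_xz", "rank", "label"}
        assert len(df) == 21


class TestFixPhases:
    def test_idempotent(self, benzene_labels):
        once = fix_phases(benzene_labels)
        twice = fix_phases(once)
        np.testing.assert_array_equal(once.mo_coefficients,
                                      twice.mo_coefficients)

    def test_largest_coefficient_positive(self, benzene_labels):
        C = benzene_labels.mo_coefficients
        for i in range(C.shape[1]):
            mu = int(np.argmax(np.abs(C[:, i])))
            assert C[mu, i] > 0

    def test_squared_observables_phase_invariant(self, ethylene_scf):
        """S^2 sums and all pair energies are unchanged by phase flips."""
        dim = fixture("ethylene_dimer").dimer(dz=3.4)
        lab = classify_orbitals(ethylene_scf)
        flipped = lab.__class__(
            scf=lab.scf,
            mo_coefficients=-lab.mo_coefficients,
            orbital_energies=lab.orbital_energies,
            labels=lab.labels,
        )
        from pistack.mopce import pair_table

        c1 = MopceContext.build(ethylene_scf, dim, labels=fix_phases(lab))
        c2 = MopceContext.build(ethylene_scf, dim, labels=flipped)
        t1, t2 = pair_table(c1), pair_table(c2)
        np.testing.assert_allclose(t1.total, t2.total, atol=1e-12)
        np.testing.assert_allclose(t1.s_ab ** 2, t2.s_ab ** 2, atol=1e-14)

    def test_cofacial_diagonal_pi_overlaps_share_sign(self, benzene_scf,
                                                      benzene_labels):
        dim = fixture("benzene").dimer(dz=3.4)
        db = dimer_basis(dim, benzene_scf.basis)
        S_ao, _ = integrals.overlap_kinetic(db.ao)
        C = benzene_labels.mo_coefficients
        C_A = embed_coefficients(db, benzene_scf, "A", coefficients=C)
        C_B = embed_coefficients(db, benzene_scf, "B", coefficients=C)
        S = C_A.T @ S_ao @ C_B
        signs = {np.sign(S[i, i]) for i in benzene_labels.pi_indices}
        assert len(signs) == 1


class TestCrossOverlap:
    def test_symmetry_forbidden_blocks_vanish_at_dy0(self, benzene_scf,
                                                     benzene_labels):
        """S(nS, mA) = 0 for arrangements preserving the sigma_xz mirror."""
        dim = fixture("benzene").dimer(dx=1.3, dy=0.0, dz=3.4)
        ctx = MopceContext.build(benzene_scf, dim, labels=benzene_labels)
        xs = ctx.cross_overlap()
        for i in benzene_labels.pi_by_parity("S"):
            for j in benzene_labels.pi_by_parity("A"):
                assert abs(xs.matrix[i, j]) < 1e-10
                assert abs(xs.matrix[j, i]) < 1e-10
        gr = squared_overlap_sums(xs)
        assert gr["S2(piS-piA)"] < 1e-20

    def test_separated_limit(self, he_scf):
        dim = fixture("he2").dimer(dz=50.0)
        ctx = MopceContext.build(he_scf, dim)
        assert np.abs(ctx.S).max() < 1e-12

    def test_overlap_bounded_by_one(self, ethylene_scf, ethylene_labels):
        dim = fixture("ethylene_dimer").dimer(dz=3.4)
        ctx = MopceContext.build(ethylene_scf, dim, labels=ethylene_labels)
        assert np.abs(ctx.S).max() <= 1.0 + 1e-9


class TestCountPairs:
    def test_benzene_all_pairs(self, benzene_labels):
        assert count_pairs(benzene_labels, benzene_labels, "all") == 441

    def test_partition_completeness(self, benzene_labels):
        total = count_pairs(benzene_labels, benzene_labels, "all")
        parts = (count_pairs(benzene_labels, benzene_labels, "pi-pi")
                 + count_pairs(benzene_labels, benzene_labels, "pi-sigma")
                 + count_pairs(benzene_labels, benzene_labels, "sigma-sigma"))
        assert total == parts

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(npi_a=st.integers(0, 15), nsig_a=st.integers(1, 70),
           npi_b=st.integers(0, 15), nsig_b=st.integers(1, 70))
    def test_partition_identity_synthetic(self, npi_a, nsig_a, npi_b, nsig_b):
        """count(all) = pipi + pisigma + sigmasigma for arbitrary label sets."""

        class FakeLabels:
            def __init__(self, npi, nsig):
                self.pi_indices = list(range(npi))
                self.sigma_indices = list(range(npi, npi + nsig))

        a, b = FakeLabels(npi_a, nsig_a), FakeLabels(npi_b, nsig_b)
        assert (count_pairs(a, b, "all")
                == count_pairs(a, b, "pi-pi")
                + count_pairs(a, b, "pi-sigma")
                + count_pairs(a, b, "sigma-sigma"))
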