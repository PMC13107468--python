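"""Pair decomposition of the exchange repulsion: identities and oracles."""

import numpy as np
import pytest

from pistack import oracles
from pistack.fixtures import fixture
from pistack.mopce import (MopceContext, group_sums, pair_components,
                           pair_table, squared_overlap_sums)
from pistack.scf import run_rhf

COMPONENTS = ("e_xi", "e_xr2", "e_xr3", "e_xr4", "e_xrb")


def _ctx(scf, name, dz, mode="monomer"):
    dim = fixture(name).dimer(dz=dz)
    return MopceContext.build(scf, dim, mode=mode)


class TestOracleEquivalence:
    """Optimized tensor evaluation vs the explicit loop-based reference."""

    @pytest.mark.parametrize("dz", [2.5, 3.0, 4.0])
    def test_he2(self, he_scf, dz):
        ctx = _ctx(he_scf, "he2", dz)
        ref = oracles.naive_pair_components(0, 0, ctx)
        got = pair_components(0, 0, ctx)
        for k in COMPONENTS:
            assert abs(getattr(got, k) - ref[k]) < 1e-10, k
        assert abs(got.total - ref["total"]) < 1e-10

    @pytest.mark.parametrize("dz", [3.0, 3.4, 4.5])
    def test_h2_dimer(self, h2_scf, dz):
        ctx = _ctx(h2_scf, "h2_dimer", dz)
        ref = oracles.naive_pair_components(0, 0, ctx)
        got = pair_components(0, 0, ctx)
        for k in COMPONENTS:
            assert abs(getattr(got, k) - ref[k]) < 1e-10, k

    @pytest.mark.parametrize("dz", [3.0, 3.4, 4.0])
    def test_ethylene_dimer_all_pairs(self, ethylene_scf, dz):
        ctx = _ctx(ethylene_scf, "ethylene_dimer", dz)
        tab = pair_table(ctx)
        n = ethylene_scf.n_occupied
        rng = np.random.default_rng(3)
        pairs = {(a, b) for a, b in
                 zip(rng.integers(0, n, 6), rng.integers(0, n, 6))}
        pairs |= {(0, 0), (n - 1, n - 1)}
        for (a, b) in pairs:
            ref = oracles.naive_pair_components(a, b, ctx)
            for k in COMPONENTS:
                assert abs(getattr(tab, k)[a, b] - ref[k]) < 1e-10, (a, b, k)


class TestComponentIdentities:
    def test_component_sum_identity_pairwise(self, ethylene_scf):
        """total == e_xi + e_xr2 + e_xr3 + e_xr4 + e_xrb, and equals the
        direct evaluation of the defining expression, pair by pair."""
        ctx = _ctx(ethylene_scf, "ethylene_dimer", 3.4)
        tab = pair_table(ctx)
        assert np.abs(tab.total - tab.e_direct).max() < 1e-12

    def test_eigenvalue_vs_potential_form_ghost_mode(self, h2_scf, he_scf,
                                                     ethylene_scf):
        """For counterpoise-canonical orbitals the two expressions for the
        two-index term coincide and the basis-error term vanishes."""
        for scf, name in ((he_scf, "he2"), (h2_scf, "h2_dimer"),
                          (ethylene_scf, "ethylene_dimer")):
            ctx = _ctx(scf, name, 3.4, mode="dimer_ghost")
            tab = pair_table(ctx)
            assert np.abs(tab.e_xr2_eigenvalue_form - tab.e_xr2).max() < 1e-7
            assert np.abs(tab.e_xrb).max() < 1e-7

    def test_eq6_eq7_difference_equals_basis_error(self, ethylene_scf):
        """In the monomer-embedded basis the difference between the two
        E_xr2 expressions is exactly the basis-error term."""
        ctx = _ctx(ethylene_scf, "ethylene_dimer", 3.4)
        tab = pair_table(ctx)
        diff = tab.e_xr2 - tab.e_xr2_eigenvalue_form
        np.testing.assert_allclose(diff, tab.e_xrb, atol=1e-10)

    def test_separated_limit_all_components_vanish(self, he_scf):
        ctx = _ctx(he_scf, "he2", 50.0)
        pc = pair_components(0, 0, ctx)
        for k in COMPONENTS:
            assert abs(getattr(pc, k)) < 1e-12

    def test_exchange_integral_part_nonpositive(self, ethylene_scf):
        tab = pair_table(_ctx(ethylene_scf, "ethylene_dimer", 3.4))
        assert tab.e_xi.max() <= 1e-12

    def test_single_orbital_monomer_four_index_reduction(self, h2_scf):
        """With one occupied orbital per monomer the four-index term
        collapses to 2 S [4(ab|ab) - (ab|ab) - (aa|bb)] S."""
        ctx = _ctx(h2_scf, "h2_dimer", 3.4)
        g1 = ctx.eri_occ.g_abab
        g2 = ctx.eri_occ.g_aabb
        S = ctx.S[0, 0]
        hand = 2.0 * S * (4.0 * g1[0, 0, 0, 0] - g1[0, 0, 0, 0]
                          - g2[0, 0, 0, 0]) * S
        pc = pair_components(0, 0, ctx)
        assert abs(pc.e_xr4 - hand) < 1e-12

    def test_out_of_range_pair_rejected(self, he_scf):
        ctx = _ctx(he_scf, "he2", 3.0)
        with pytest.raises(IndexError):
            pair_components(1, 0, ctx)


class TestPairTable:
    def test_table_sums_equal_entry_sums_exactly(self, ethylene_scf):
        tab = pair_table(_ctx(ethylene_scf, "ethylene_dimer", 3.4))
        sums = tab.component_sums()
        assert sums["e_xr"] == pytest.approx(tab.total.sum(), abs=1e-14)
        for k in COMPONENTS:
            assert sums[k] == pytest.approx(getattr(tab, k).sum(), abs=1e-14)

    def test_cofacial_exchange_symmetry(self, ethylene_scf):
        """Identical monomers cofacially stacked: table symmetric in (a,b)."""
        tab = pair_table(_ctx(ethylene_scf, "ethylene_dimer", 3.4))
        assert np.abs(tab.total - tab.total.T).max() < 1e-10

    def test_total_exchange_repulsion_positive(self, ethylene_scf, h2_scf):
        for scf, name in ((ethylene_scf, "ethylene_dimer"),
                          (h2_scf, "h2_dimer")):
            tab = pair_table(_ctx(scf, name, 3.4))
            assert tab.exchange_repulsion > 0

    def test_symmetry_forbidden_pair_is_pure_exchange_integral(
            self, ethylene_scf, ethylene_labels):
        """At dy=0 a (S, A)-parity pair has zero overlap, so its term
        reduces to -2(ab|ba) <= 0."""
        dim = fixture("ethylene_dimer").dimer(dx=1.0, dy=0.0, dz=3.4)
        ctx = MopceContext.build(ethylene_scf, dim, labels=ethylene_labels)
        tab = pair_table(ctx)
        # find a pair with vanishing overlap (sigma_xz-forbidden)
        forbidden = np.argwhere(np.abs(tab.s_ab) < 1e-12)
        assert len(forbidden) > 0
        for a, b in forbidden:
            assert abs(tab.total[a, b] - tab.e_xi[a, b]) < 1e-10
            assert tab.total[a, b] <= 1e-12

    def test_csv_export_schema(self, ethylene_scf, tmp_path):
        tab = pair_table(_ctx(ethylene_scf, "ethylene_dimer", 3.4))
        path = tmp_path / "pairs.csv"
        tab.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert list(df.columns) == [
            "a_index", "b_index", "a_label", "b_label", "s_ab", "s_ab_sq",
            "e_xi", "e_xr2", "e_xr3", "e_xr4", "e_xrb", "e_total", "e_rep"]
        assert len(df) == ethylene_scf.n_occupied ** 2


class TestGroupSums:
    def test_class_partition_completeness(self, ethylene_scf):
        tab = pair_table(_ctx(ethylene_scf, "ethylene_dimer", 3.4))
        ge = group_sums(tab)
        assert abs(ge.total - tab.exchange_repulsion) < 1e-10
        assert abs((ge.e_piS_piS + ge.e_piA_piA + ge.e_piS_piA)
                   - ge.e_pi_pi) < 1e-10

    def test_squared_overlap_groups_nonnegative(self, ethylene_scf):
        ctx = _ctx(ethylene_scf, "ethylene_dimer", 3.4)
        gr = squared_overlap_sums(ctx.cross_overlap())
        for v in gr.values():
            assert v >= 0.0

    def test_grouped_s2_matches_direct_sum(self, ethylene_scf):
        ctx = _ctx(ethylene_scf, "ethylene_dimer", 3.4)
        gr = squared_overlap_sums(ctx.cross_overlap())
        assert gr["S2(all)"] == pytest.approx(float((ctx.S ** 2).sum()),
                                              abs=1e-14)


class TestHeitlerLondonReference:
    @pytest.mark.parametrize("name,scf_fixture,dz", [
        ("he2", "he_scf", 3.0),
        ("he2", "he_scf", 3.5),
        ("h2_dimer", "h2_scf", 3.0),
        ("h2_dimer", "h2_scf", 3.4),
    ])
    def test_total_within_5_percent_of_hl(self, name, scf_fixture, dz, request):
        """The pair-decomposition total reproduces the independent
        antisymmetrized-product exchange energy within 5%."""
        scf = request.getfixturevalue(scf_fixture)
        ctx = _ctx(scf, name, dz)
        tab = pair_table(ctx)
        hl = oracles.hl_exchange(ctx)
        assert hl > 0
        assert abs(tab.exchange_repulsion - hl) / abs(hl) < 0.05

    def test_signs_agree_at_bonding_distances(self, he_scf):
        for dz in (3.0, 4.0, 5.0):
            ctx = _ctx(he_scf, "he2", dz)
            tab = pair_table(ctx)
            hl = oracles.hl_exchange(ctx)
            assert np.sign(tab.exchange_repulsion) == np.sign(hl)

    def test_monotonic_decay_with_separation(self, h2_scf):
        vals, hls = [], []
        for dz in (3.0, 4.0, 5.0, 6.0):
            ctx = _ctx(h2_scf, "h2_dimer", dz)
            vals.append(pair_table(ctx).exchange_repulsion)
            hls.append(oracles.hl_exchange(ctx))
        assert all(np.diff(vals) < 0)
        assert all(np.diff(hls) < 0)


class TestProportionality:
    def test_diagonal_pi_pair_tracks_squared_overlap(self, ethylene_scf,
                                                     ethylene_labels):
        """Along an x-scan the dominant two-index term of a diagonal pi
        pair is essentially proportional to its squared overlap."""
        i = ethylene_labels.index_of("1S")
        e2, s2 = [], []
        for dx in np.linspace(0.0, 3.0, 7):
            dim = fixture("ethylene_dimer").dimer(dx=dx, dz=3.4)
            ctx = MopceContext.build(ethylene_scf, dim,
                                     labels=ethylene_labels)
            tab = pair_table(ctx)
            e2.append(tab.e_xr2[i, i])
            s2.append(tab.s_ab[i, i] ** 2)
        r = np.corrcoef(e2, s2)[0, 1]
        assert r > 0.99
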