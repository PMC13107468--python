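"""Molecular Orbital-Pair Contributions to the Exchange repulsion (MOPCE).

The first-order exchange (Pauli) repulsion between two closed-shell
monomers, E_xr, is partitioned into contributions E_xr(a, b) attached to
one occupied orbital a of monomer A and one occupied orbital b of B:

    E_xr(a,b) = -2(ab|ba)
                + 2 S_ab { -2 F_ab + sum_a' F_aa' S_a'b + sum_b' S_ab' F_b'b
                           + sum_a'b' [4(ab|a'b') - (ab'|a'b) - (aa'|bb')] S_a'b' }

with F the Fock operator of the dimer built from the two monomer densities
and S_ab the inter-monomer MO overlap.  Each pair term splits into

    E_xr(a,b) = E_xi + E_xr2 + E_xr3 + E_xr4 + E_xrb

* E_xi  = -2(ab|ba), the (attractive) exchange-integral part;
* E_xr2 = -2 S_ab [(b|V_A|a) + (a|V_B|b)], the dominant two-index part,
  where V_X = v_X + 2J_X - K_X is the effective potential of monomer X.
  For orbitals canonical in the full dimer basis this equals
  -2(eps_a + eps_b) S_ab^2 + 4 S_ab T_ab;
* E_xr3, the three-index coupling through the partner potential;
* E_xr4, the four-index two-electron coupling;
* E_xrb, a finite-basis error term that vanishes identically when the
  orbitals are canonical in the full dimer basis (counterpoise mode).

The pair-by-pair component sum identity holds exactly with the potential
(two-index) form of E_xr2; the eigenvalue form is evaluated alongside and
their difference -- which equals E_xrb analytically -- is reported as a
diagnostic.

Groupings: pi-pi / pi-sigma / sigma-sigma by orbital class, and within
pi-pi the S/A mirror-parity blocks (piS-piS, piA-piA, piS-piA), together
with the matching summed squared overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import integrals
from .estruct import (ContractError, OccERIBlock, OperatorMatrices,
                      dimer_basis, embed_coefficients, occ_eri_block,
                      operator_matrices)
from .geometry import DimerArrangement
from .orbital_analysis import (CrossOverlap, LabeledOrbitals, classify_orbitals,
                               cross_overlap, fix_phases)
from .scf import SCFResult, run_rhf
from .units import HARTREE_TO_KJMOL

__all__ = [
    "PairComponents",
    "MOPCEPairTable",
    "GroupedExchange",
    "MopceContext",
    "pair_components",
    "pair_table",
    "group_sums",
    "squared_overlap_sums",
]


@dataclass(frozen=True)
class PairComponents:
    """All exchange-repulsion components of one orbital pair (Hartree)."""

    a: int
    b: int
    e_xi: float
    e_xr2: float
    e_xr3: float
    e_xr4: float
    e_xrb: float
    s_ab: float
    e_xr2_eigenvalue_form: float

    @property
    def total(self) -> float:
        return self.e_xi + self.e_xr2 + self.e_xr3 + self.e_xr4 + self.e_xrb

    @property
    def e_rep(self) -> float:
        """Repulsive remainder: everything except the exchange integral."""
        return self.total - self.e_xi

    @property
    def s_ab_sq(self) -> float:
        return self.s_ab ** 2

    @property
    def eq6_vs_eq7(self) -> float:
        """Difference between the eigenvalue and potential forms of E_xr2
        (equals E_xrb analytically)."""
        return self.e_xr2_eigenvalue_form - self.e_xr2


class MopceContext:
    """Everything needed to evaluate pair terms for one arrangement.

    Builds (once) the dimer AO integrals, the embedded occupied orbital
    sets of both monomers, the operator matrices and the occupied-block
    MO two-electron integrals.
    """

    def __init__(self, scfA: SCFResult, scfB: SCFResult,
                 labelsA: LabeledOrbitals, labelsB: LabeledOrbitals,
                 dimer: DimerArrangement, ops: OperatorMatrices,
                 eri_occ: OccERIBlock):
        self.scfA, self.scfB = scfA, scfB
        self.labelsA, self.labelsB = labelsA, labelsB
        self.dimer = dimer
        self.ao_eri = None
        self.ops = ops
        self.eri_occ = eri_occ
        C_A, C_B = ops.C_A, ops.C_B
        self.S = C_A.T @ ops.ao_overlap @ C_B
        self.T = C_A.T @ ops.kinetic @ C_B
        self.F_ab = C_A.T @ ops.fock @ C_B
        self.F_aa = C_A.T @ ops.fock @ C_A
        self.F_bb = C_B.T @ ops.fock @ C_B
        self.FA_ab = C_A.T @ ops.fock_A @ C_B
        self.FB_ab = C_A.T @ ops.fock_B @ C_B
        self.FA_aa = C_A.T @ ops.fock_A @ C_A
        self.FB_bb = C_B.T @ ops.fock_B @ C_B
        # effective-potential matrix elements
        self.VA_ba = C_B.T @ ops.pot_A @ C_A   # (b|V_A|a)
        self.VB_ab = C_A.T @ ops.pot_B @ C_B   # (a|V_B|b)
        self.VB_aa = C_A.T @ ops.pot_B @ C_A
        self.VA_bb = C_B.T @ ops.pot_A @ C_B
        self.eps_a = scfA.orbital_energies
        self.eps_b = scfB.orbital_energies

    @property
    def mode(self) -> str:
        return self.scfA.basis_mode

    @property
    def shape(self):
        return self.S.shape

    @classmethod
    def build(cls, monomer_scf: SCFResult, dimer: DimerArrangement,
              mode: str = "monomer",
              max_memory_gb: float = integrals.DEFAULT_MAX_MEMORY_GB,
              labels: LabeledOrbitals | None = None) -> "MopceContext":
        """Assemble the full context for identical monomers.

        ``monomer_scf`` is the fixed monomer's SCF; in ``dimer_ghost`` mode
        it is recomputed in the counterpoise basis of this arrangement.
        The mobile monomer's orbitals are the translated copy in both modes.
        """
        if mode == "dimer_ghost":
            scfA = run_rhf(monomer_scf.molecule, monomer_scf.basis,
                           ghost_partner=dimer.mobile,
                           max_memory_gb=max_memory_gb)
        elif mode == "monomer":
            scfA = monomer_scf
        else:
            raise ContractError(f"unknown basis mode {mode!r}")
        scfB = scfA
        if labels is None or mode == "dimer_ghost":
            labA = fix_phases(classify_orbitals(scfA))
        else:
            labA = labels
        labB = labA
        db = dimer_basis(dimer, scfA.basis)
        C_A = embed_coefficients(db, scfA, "A", coefficients=labA.mo_coefficients)
        C_B = embed_coefficients(db, scfB, "B", coefficients=labB.mo_coefficients)
        ao_eri = integrals.eri_dense(db.ao, max_memory_gb)
        ops = operator_matrices(dimer, scfA, scfB, scfA.basis, ao_eri=ao_eri,
                                C_A=C_A, C_B=C_B, max_memory_gb=max_memory_gb)
        eri_occ = occ_eri_block(scfA, scfB, scfA.basis, dimer, ao_eri=ao_eri,
                                C_A=C_A, C_B=C_B, max_memory_gb=max_memory_gb)
        ctx = cls(scfA, scfB, labA, labB, dimer, ops, eri_occ)
        ctx.ao_eri = ao_eri  # retained for oracle cross-checks
        return ctx

    def cross_overlap(self) -> CrossOverlap:
        return cross_overlap(self.labelsA, self.labelsB, self.ops)


def _component_matrices(ctx: MopceContext):
    """All component matrices over (a, b) at once (vectorized)."""
    S = ctx.S
    g1 = ctx.eri_occ.g_abab
    g2 = ctx.eri_occ.g_aabb

    e_xi = -2.0 * np.einsum("abab->ab", g1)
    # coupling kernel: sum_a'b' [4(ab|a'b') - (ab'|a'b) - (aa'|bb')] S_a'b'
    t1 = 4.0 * np.tensordot(g1, S, axes=([2, 3], [0, 1]))
    t2 = np.einsum("aqpb,pq->ab", g1, S, optimize=True)
    t3 = np.einsum("apbq,pq->ab", g2, S, optimize=True)
    kernel = t1 - t2 - t3
    e_xr4 = 2.0 * S * kernel

    e_xr2 = -2.0 * S * (ctx.VA_ba.T + ctx.VB_ab)
    e_xr2_eig = (-2.0 * (ctx.eps_a[:, None] + ctx.eps_b[None, :]) * S ** 2
                 + 4.0 * S * ctx.T)
    e_xr3 = 2.0 * S * (ctx.VB_aa @ S + S @ ctx.VA_bb.T)
    e_xrb = 2.0 * S * (-ctx.FA_ab + ctx.FA_aa @ S - ctx.FB_ab + S @ ctx.FB_bb)
    # direct evaluation of the defining expression, as a cross-check
    e_direct = e_xi + 2.0 * S * (-2.0 * ctx.F_ab + ctx.F_aa @ S
                                 + S @ ctx.F_bb + kernel)
    return e_xi, e_xr2, e_xr3, e_xr4, e_xrb, e_xr2_eig, e_direct


def pair_components(a: int, b: int, ctx: MopceContext) -> PairComponents:
    """Exchange-repulsion components of the single orbital pair (a, b)."""
    na, nb = ctx.shape
    if not (0 <= a < na and 0 <= b < nb):
        raise IndexError(
            f"orbital pair ({a}, {b}) outside occupied ranges ({na}, {nb})"
        )
    S = ctx.S
    g1 = ctx.eri_occ.g_abab
    g2 = ctx.eri_occ.g_aabb
    e_xi = -2.0 * g1[a, b, a, b]
    kernel = float(np.sum((4.0 * g1[a, b] - g1[a, :, :, b].T
                           - g2[a, :, b, :]) * S))
    e_xr4 = 2.0 * S[a, b] * kernel
    e_xr2 = -2.0 * S[a, b] * (ctx.VA_ba[b, a] + ctx.VB_ab[a, b])
    e_xr2_eig = (-2.0 * (ctx.eps_a[a] + ctx.eps_b[b]) * S[a, b] ** 2
                 + 4.0 * S[a, b] * ctx.T[a, b])
    e_xr3 = 2.0 * S[a, b] * (float(ctx.VB_aa[a] @ S[:, b])
                             + float(ctx.VA_bb[b] @ S[a, :]))
    e_xrb = 2.0 * S[a, b] * (-ctx.FA_ab[a, b] + float(ctx.FA_aa[a] @ S[:, b])
                             - ctx.FB_ab[a, b] + float(S[a] @ ctx.FB_bb[:, b]))
    return PairComponents(a=a, b=b, e_xi=float(e_xi), e_xr2=float(e_xr2),
                          e_xr3=float(e_xr3), e_xr4=float(e_xr4),
                          e_xrb=float(e_xrb), s_ab=float(S[a, b]),
                          e_xr2_eigenvalue_form=float(e_xr2_eig))


@dataclass
class MOPCEPairTable:
    """Component matrices over all occupied pairs plus their sums.

    Sums are accumulated in fixed row-major order over (a, b), so the
    stored sums equal the sum of the table entries exactly.
    """

    e_xi: np.ndarray
    e_xr2: np.ndarray
    e_xr3: np.ndarray
    e_xr4: np.ndarray
    e_xrb: np.ndarray
    s_ab: np.ndarray
    e_xr2_eigenvalue_form: np.ndarray
    e_direct: np.ndarray = field(repr=False, default=None)
    labels_A: LabeledOrbitals = field(repr=False, default=None)
    labels_B: LabeledOrbitals = field(repr=False, default=None)

    @property
    def total(self) -> np.ndarray:
        return self.e_xi + self.e_xr2 + self.e_xr3 + self.e_xr4 + self.e_xrb

    @property
    def e_rep(self) -> np.ndarray:
        return self.total - self.e_xi

    def _rowmajor_sum(self, M: np.ndarray) -> float:
        acc = 0.0
        for row in M:
            for v in row:
                acc += v
        return acc

    def component_sums(self) -> dict[str, float]:
        """E_xi, E_xr2, ..., E_xr totals (Hartree), fixed accumulation order."""
        out = {}
        for name in ("e_xi", "e_xr2", "e_xr3", "e_xr4", "e_xrb"):
            out[name] = self._rowmajor_sum(getattr(self, name))
        out["e_xr"] = self._rowmajor_sum(self.total)
        return out

    @property
    def exchange_repulsion(self) -> float:
        """Total E_xr in Hartree."""
        return self.component_sums()["e_xr"]

    def entry(self, a: int, b: int) -> PairComponents:
        return PairComponents(
            a=a, b=b, e_xi=float(self.e_xi[a, b]), e_xr2=float(self.e_xr2[a, b]),
            e_xr3=float(self.e_xr3[a, b]), e_xr4=float(self.e_xr4[a, b]),
            e_xrb=float(self.e_xrb[a, b]), s_ab=float(self.s_ab[a, b]),
            e_xr2_eigenvalue_form=float(self.e_xr2_eigenvalue_form[a, b]),
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Pair table in kJ/mol (overlaps dimensionless)."""
        la, lb = self.labels_A, self.labels_B
        na, nb = self.s_ab.shape
        rows = []
        for a in range(na):
            for b in range(nb):
                rows.append({
                    "a_index": a,
                    "b_index": b,
                    "a_label": la.labels[a].name if la else str(a),
                    "b_label": lb.labels[b].name if lb else str(b),
                    "s_ab": self.s_ab[a, b],
                    "s_ab_sq": self.s_ab[a, b] ** 2,
                    "e_xi": self.e_xi[a, b] * HARTREE_TO_KJMOL,
                    "e_xr2": self.e_xr2[a, b] * HARTREE_TO_KJMOL,
                    "e_xr3": self.e_xr3[a, b] * HARTREE_TO_KJMOL,
                    "e_xr4": self.e_xr4[a, b] * HARTREE_TO_KJMOL,
                    "e_xrb": self.e_xrb[a, b] * HARTREE_TO_KJMOL,
                    "e_total": self.total[a, b] * HARTREE_TO_KJMOL,
                    "e_rep": self.e_rep[a, b] * HARTREE_TO_KJMOL,
                })
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def pair_table(ctx: MopceContext) -> MOPCEPairTable:
    """Evaluate every occupied orbital pair of the arrangement."""
    e_xi, e_xr2, e_xr3, e_xr4, e_xrb, e_xr2_eig, e_direct = \
        _component_matrices(ctx)
    return MOPCEPairTable(
        e_xi=e_xi, e_xr2=e_xr2, e_xr3=e_xr3, e_xr4=e_xr4, e_xrb=e_xrb,
        s_ab=ctx.S.copy(), e_xr2_eigenvalue_form=e_xr2_eig,
        e_direct=e_direct, labels_A=ctx.labelsA, labels_B=ctx.labelsB,
    )


@dataclass(frozen=True)
class GroupedExchange:
    """Grouped exchange-repulsion sums (Hartree) and grouped S^2 sums."""

    e_pi_pi: float
    e_pi_sigma: float
    e_sigma_sigma: float
    e_piS_piS: float
    e_piA_piA: float
    e_piS_piA: float
    s2_pi_pi: float
    s2_piS_piS: float
    s2_piA_piA: float
    s2_piS_piA: float

    @property
    def total(self) -> float:
        return self.e_pi_pi + self.e_pi_sigma + self.e_sigma_sigma

    def as_kjmol(self) -> dict[str, float]:
        h = HARTREE_TO_KJMOL
        return {
            "E_xr": self.total * h,
            "E_xr(pi-pi)": self.e_pi_pi * h,
            "E_xr(pi-sigma)": self.e_pi_sigma * h,
            "E_xr(sigma-sigma)": self.e_sigma_sigma * h,
            "E_xr(piS-piS)": self.e_piS_piS * h,
            "E_xr(piA-piA)": self.e_piA_piA * h,
            "E_xr(piS-piA)": self.e_piS_piA * h,
            "S2(pi-pi)": self.s2_pi_pi,
            "S2(piS-piS)": self.s2_piS_piS,
            "S2(piA-piA)": self.s2_piA_piA,
            "S2(piS-piA)": self.s2_piS_piA,
        }


def _group_masks(labA: LabeledOrbitals, labB: LabeledOrbitals, shape):
    na, nb = shape
    pa = np.zeros(na, dtype=bool)
    pa[labA.pi_indices] = True
    pb = np.zeros(nb, dtype=bool)
    pb[labB.pi_indices] = True
    sa_ = np.zeros(na, dtype=bool)
    sa_[labA.pi_by_parity("S")] = True
    aa_ = np.zeros(na, dtype=bool)
    aa_[labA.pi_by_parity("A")] = True
    sb_ = np.zeros(nb, dtype=bool)
    sb_[labB.pi_by_parity("S")] = True
    ab_ = np.zeros(nb, dtype=bool)
    ab_[labB.pi_by_parity("A")] = True
    return pa, pb, sa_, aa_, sb_, ab_


def group_sums(table: MOPCEPairTable,
               labA: LabeledOrbitals | None = None,
               labB: LabeledOrbitals | None = None) -> GroupedExchange:
    """Class- and parity-grouped sums of the pair table."""
    labA = labA or table.labels_A
    labB = labB or table.labels_B
    E = table.total
    S2 = table.s_ab ** 2
    if E.shape != (labA.n_occupied, labB.n_occupied):
        raise ContractError("label sets do not match the pair table")
    pa, pb, sa_, aa_, sb_, ab_ = _group_masks(labA, labB, E.shape)

    def gsum(M, ma, mb):
        return float(M[np.ix_(ma, mb)].sum())

    e_pipi = gsum(E, pa, pb)
    e_pisig = gsum(E, pa, ~pb) + gsum(E, ~pa, pb)
    e_sigsig = gsum(E, ~pa, ~pb)
    return GroupedExchange(
        e_pi_pi=e_pipi,
        e_pi_sigma=e_pisig,
        e_sigma_sigma=e_sigsig,
        e_piS_piS=gsum(E, sa_, sb_),
        e_piA_piA=gsum(E, aa_, ab_),
        e_piS_piA=gsum(E, sa_, ab_) + gsum(E, aa_, sb_),
        s2_pi_pi=gsum(S2, pa, pb),
        s2_piS_piS=gsum(S2, sa_, sb_),
        s2_piA_piA=gsum(S2, aa_, ab_),
        s2_piS_piA=gsum(S2, sa_, ab_) + gsum(S2, aa_, sb_),
    )


def squared_overlap_sums(S: CrossOverlap,
                         labA: LabeledOrbitals | None = None,
                         labB: LabeledOrbitals | None = None) -> dict[str, float]:
    """Grouped sums of squared inter-monomer overlaps."""
    labA = labA or S.labels_A
    labB = labB or S.labels_B
    S2 = S.matrix ** 2
    pa, pb, sa_, aa_, sb_, ab_ = _group_masks(labA, labB, S2.shape)

    def gsum(ma, mb):
        return float(S2[np.ix_(ma, mb)].sum())

    return {
        "S2(all)": float(S2.sum()),
        "S2(pi-pi)": gsum(pa, pb),
        "S2(pi-sigma)": gsum(pa, ~pb) + gsum(~pa, pb),
        "S2(sigma-sigma)": gsum(~pa, ~pb),
        "S2(piS-piS)": gsum(sa_, sb_),
        "S2(piA-piA)": gsum(aa_, ab_),
        "S2(piS-piA)": gsum(sa_, ab_) + gsum(aa_, sb_),
    }
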