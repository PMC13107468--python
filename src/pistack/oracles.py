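"""Independent brute-force references for testing.

Everything here deliberately avoids the optimized code paths of the main
modules: the pair decomposition is re-evaluated with explicit nested loops
from its defining expression, the Heitler-London exchange comes from the
energy of the explicitly antisymmetrized product determinant (Loewdin
inverse-overlap density), s-type repulsion integrals have a closed form
checked against the integral engine, and box-model overlaps are computed
by numerical quadrature.  All functions refuse systems beyond small fixed
sizes -- they are correctness anchors, not production paths.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad
from scipy.special import erf

from . import integrals
from .basis import basis_for_molecule
from .geometry import Molecule
from .units import BOHR_PER_ANGSTROM

__all__ = [
    "OracleSizeError",
    "textbook_rhf_energy",
    "naive_pair_components",
    "hl_exchange",
    "s_primitive_eri",
    "pib_overlap_quadrature",
]


class OracleSizeError(ValueError):
    """System too large for a brute-force oracle evaluation."""


# ---------------------------------------------------------------- RHF oracle

def textbook_rhf_energy(mol: Molecule, basis, max_nao: int = 40,
                        maxiter: int = 500, tol: float = 1e-12) -> float:
    """Plain damped Roothaan iteration (no DIIS, no guess tricks).

    Independent of :mod:`pistack.scf`; shares only the integral engine.
    """
    ao = basis_for_molecule(mol, basis)
    if ao.nao > max_nao:
        raise OracleSizeError(f"{ao.nao} AOs exceeds oracle limit {max_nao}")
    S, T = integrals.overlap_kinetic(ao)
    V = integrals.nuclear_attraction(ao)
    H = T + V
    eri = integrals.eri_dense(ao)
    Enuc = integrals.nuclear_repulsion(ao.charges, ao.charge_pos)
    nocc = mol.n_electrons // 2

    sval, svec = np.linalg.eigh(S)
    X = svec / np.sqrt(sval)
    F = H.copy()
    P = np.zeros_like(H)
    E_old = 0.0
    for it in range(maxiter):
        Fp = X.T @ F @ X
        _, Cp = np.linalg.eigh(Fp)
        C = X @ Cp
        Cocc = C[:, :nocc]
        P_new = Cocc @ Cocc.T
        P = 0.5 * (P + P_new) if it > 0 else P_new
        J = np.einsum("pqrs,rs->pq", eri, P)
        K = np.einsum("prqs,rs->pq", eri, P)
        F = H + 2 * J - K
        E = float(np.sum(P * (H + F))) + Enuc
        if abs(E - E_old) < tol:
            return E
        E_old = E
    raise RuntimeError("oracle RHF did not converge")


# ------------------------------------------------- pair-decomposition oracle

def _mo_eri(ao_eri, Cp, Cq, Cr, Cs):
    """(pq|rs) MO transform by four successive single-index contractions,
    contracted in reverse index order (distinct from the production path)."""
    t = np.tensordot(ao_eri, Cs, axes=(3, 0))
    t = np.tensordot(t, Cr, axes=(2, 0))
    t = np.tensordot(t, Cq, axes=(1, 0))
    t = np.tensordot(t, Cp, axes=(0, 0))
    # result indexed [s-last ... ]: axes now (q? ...) -> reorder
    return np.transpose(t, (3, 2, 1, 0))


def naive_pair_components(a: int, b: int, ctx, max_nao: int = 80) -> dict:
    """Loop-based evaluation of every component of one pair term.

    Evaluates the defining pair expression and its component split with
    explicit sums over coupling orbitals, using its own MO-integral
    transform of the raw dimer AO tensor.  Returns a dict with keys
    e_xi, e_xr2, e_xr3, e_xr4, e_xrb, total, e_xr2_eigenvalue_form.
    """
    ops = ctx.ops
    nao = ops.ao_overlap.shape[0]
    if nao > max_nao:
        raise OracleSizeError(f"{nao} AOs exceeds oracle limit {max_nao}")
    ao_eri = getattr(ctx, "ao_eri", None)
    if ao_eri is None:
        from .estruct import dimer_basis

        db = dimer_basis(ctx.dimer, ctx.scfA.basis)
        ao_eri = integrals.eri_dense(db.ao)
    C_A, C_B = ops.C_A, ops.C_B
    na, nb = C_A.shape[1], C_B.shape[1]

    g_abab = _mo_eri(ao_eri, C_A, C_B, C_A, C_B)   # (a b | a' b')
    g_aabb = _mo_eri(ao_eri, C_A, C_A, C_B, C_B)   # (a a' | b b')

    S = C_A.T @ ops.ao_overlap @ C_B
    T = C_A.T @ ops.kinetic @ C_B
    F = ops.fock
    FA, FB = ops.fock_A, ops.fock_B
    VA, VB = ops.pot_A, ops.pot_B
    F_ab = C_A.T @ F @ C_B
    F_aa = C_A.T @ F @ C_A
    F_bb = C_B.T @ F @ C_B

    e_xi = -2.0 * g_abab[a, b, a, b]

    # curly-bracket sums, explicit loops
    s1 = 0.0
    for ap in range(na):
        s1 += F_aa[a, ap] * S[ap, b]
    s2 = 0.0
    for bp in range(nb):
        s2 += S[a, bp] * F_bb[bp, b]
    s4 = 0.0
    for ap in range(na):
        for bp in range(nb):
            s4 += (4.0 * g_abab[a, b, ap, bp] - g_abab[a, bp, ap, b]
                   - g_aabb[a, ap, b, bp]) * S[ap, bp]
    total = e_xi + 2.0 * S[a, b] * (-2.0 * F_ab[a, b] + s1 + s2 + s4)

    e_xr4 = 2.0 * S[a, b] * s4
    vba = float(C_B[:, b] @ VA @ C_A[:, a])
    vab = float(C_A[:, a] @ VB @ C_B[:, b])
    e_xr2 = -2.0 * S[a, b] * (vba + vab)
    s3 = 0.0
    for ap in range(na):
        s3 += float(C_A[:, a] @ VB @ C_A[:, ap]) * S[ap, b]
    for bp in range(nb):
        s3 += float(C_B[:, b] @ VA @ C_B[:, bp]) * S[a, bp]
    e_xr3 = 2.0 * S[a, b] * s3
    sb_ = 0.0
    for ap in range(na):
        sb_ += float(C_A[:, a] @ FA @ C_A[:, ap]) * S[ap, b]
    for bp in range(nb):
        sb_ += float(C_B[:, b] @ FB @ C_B[:, bp]) * S[a, bp]
    e_xrb = 2.0 * S[a, b] * (-float(C_A[:, a] @ FA @ C_B[:, b])
                             - float(C_B[:, b] @ FB @ C_A[:, a]) + sb_)

    eps_a = ctx.scfA.orbital_energies[a]
    eps_b = ctx.scfB.orbital_energies[b]
    e_xr2_eig = -2.0 * (eps_a + eps_b) * S[a, b] ** 2 + 4.0 * S[a, b] * T[a, b]
    return {
        "e_xi": float(e_xi),
        "e_xr2": float(e_xr2),
        "e_xr3": float(e_xr3),
        "e_xr4": float(e_xr4),
        "e_xrb": float(e_xrb),
        "total": float(total),
        "e_xr2_eigenvalue_form": float(e_xr2_eig),
    }


# -------------------------------------------- Heitler-London exchange oracle

def hl_exchange(ctx, max_occ: int = 4) -> float:
    """First-order (Heitler-London) exchange energy, Hartree.

    Energy of the antisymmetrized product of the two monomer determinants
    (a single determinant over the union of the occupied orbitals, with
    the Loewdin inverse-overlap density) minus the monomer energies and
    the classical electrostatic interaction.  Exact in the inter-monomer
    overlap; agrees with an S^2 truncation to O(S^4).
    """
    ops = ctx.ops
    C_A, C_B = ops.C_A, ops.C_B
    if C_A.shape[1] > max_occ or C_B.shape[1] > max_occ:
        raise OracleSizeError(
            f"oracle limited to {max_occ} occupied orbitals per monomer"
        )
    ao_eri = getattr(ctx, "ao_eri", None)
    if ao_eri is None:
        from .estruct import dimer_basis

        db = dimer_basis(ctx.dimer, ctx.scfA.basis)
        ao_eri = integrals.eri_dense(db.ao)

    Ssp = ops.ao_overlap
    T = ops.kinetic
    vA, vB = ops.v_nuc_A, ops.v_nuc_B
    h = T + vA + vB
    bohr = BOHR_PER_ANGSTROM
    za = ctx.dimer.fixed.atomic_numbers.astype(float)
    ra = ctx.dimer.fixed.coords * bohr
    rb = ctx.dimer.mobile.coords * bohr
    Enn_A = integrals.nuclear_repulsion(za, ra)
    Enn_B = integrals.nuclear_repulsion(za, rb)
    Enn_cross = 0.0
    for i in range(len(za)):
        for j in range(len(za)):
            Enn_cross += za[i] * za[j] / np.linalg.norm(ra[i] - rb[j])

    def jk(D):
        J = np.tensordot(ao_eri, D, axes=([2, 3], [0, 1]))
        K = np.tensordot(np.transpose(ao_eri, (0, 2, 1, 3)), D,
                         axes=([2, 3], [0, 1]))
        return J, K

    def closed_shell_energy(D, hmat, enn):
        J, K = jk(D)
        return float(2 * np.sum(D * hmat) + 2 * np.sum(D * J)
                     - np.sum(D * K)) + enn

    # monomer energies in the dimer-embedded representation
    P_A = C_A @ C_A.T
    P_B = C_B @ C_B.T
    E_A = closed_shell_energy(P_A, T + vA, Enn_A)
    E_B = closed_shell_energy(P_B, T + vB, Enn_B)

    # classical electrostatic interaction of the unperturbed monomers
    J_B, _ = jk(P_B)
    E_elst = (4.0 * np.sum(P_A * J_B) + 2.0 * np.sum(P_A * vB)
              + 2.0 * np.sum(P_B * vA) + Enn_cross)

    # antisymmetrized product determinant
    C = np.hstack([C_A, C_B])
    M = C.T @ Ssp @ C
    D = C @ np.linalg.inv(M) @ C.T
    E_det = closed_shell_energy(D, h, Enn_A + Enn_B + Enn_cross)

    return E_det - E_A - E_B - E_elst


# ------------------------------------------------------- integral references

def s_primitive_eri(alpha, A, beta, B, gamma, Cc, delta, Dd) -> float:
    """(ab|cd) for four normalized s-type primitive Gaussians, closed form.

    Positions in Bohr.  Uses scipy's erf for the Boys function, fully
    independent of the engine's Boys recursion.
    """
    A, B, Cc, Dd = map(np.asarray, (A, B, Cc, Dd))
    p = alpha + beta
    q = gamma + delta
    P = (alpha * A + beta * B) / p
    Q = (gamma * Cc + delta * Dd) / q
    nab = (2 * alpha / np.pi) ** 0.75 * (2 * beta / np.pi) ** 0.75
    ncd = (2 * gamma / np.pi) ** 0.75 * (2 * delta / np.pi) ** 0.75
    kab = math.exp(-alpha * beta / p * float(np.sum((A - B) ** 2)))
    kcd = math.exp(-gamma * delta / q * float(np.sum((Cc - Dd) ** 2)))
    Tbar = p * q / (p + q) * float(np.sum((P - Q) ** 2))
    if Tbar < 1e-13:
        f0 = 1.0
    else:
        f0 = 0.5 * math.sqrt(math.pi / Tbar) * erf(math.sqrt(Tbar))
    return (nab * ncd * kab * kcd * 2 * math.pi ** 2.5
            / (p * q * math.sqrt(p + q)) * f0)


def pib_overlap_quadrature(n: int, m: int, a: float) -> float:
    """Box-state overlap by numerical quadrature of the defining integral."""
    if a >= 1.0:
        return 0.0

    def f(x):
        return 2.0 * math.sin(n * math.pi * x) * math.sin(m * math.pi * (x - a))

    val, _ = quad(f, a, 1.0, limit=200, epsabs=1e-13, epsrel=1e-13)
    return val
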