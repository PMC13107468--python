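"""Restricted Hartree–Fock for closed-shell monomers.

DIIS-accelerated Roothaan iterations over the built-in integral engine.
Supports a counterpoise ("dimer ghost") basis: a partner molecule whose
atoms contribute basis functions but no nuclei or electrons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import integrals
from .basis import AOBasis, BasisSpec, basis_for_molecule, _as_spec
from .geometry import GeometryError, Molecule

__all__ = ["SCFResult", "SCFError", "run_rhf"]

ENERGY_TOL = 1e-10
DRMS_TOL = 1e-8
MAX_ITER = 200


class SCFError(RuntimeError):
    """SCF failed to converge; carries iteration diagnostics."""

    def __init__(self, message, history=None):
        super().__init__(message)
        self.history = history or []


@dataclass
class SCFResult:
    """Converged restricted SCF solution of one monomer.

    ``mo_coefficients`` holds the occupied MOs only (nao x nocc) over the
    AO basis recorded in ``ao_basis``; ``basis_mode`` is "monomer" when the
    basis contains only the molecule's own functions and "dimer_ghost" when
    counterpoise partner functions were present.
    """

    mo_coefficients: np.ndarray
    orbital_energies: np.ndarray
    n_occupied: int
    total_energy: float
    converged: bool
    basis_mode: str
    molecule: Molecule
    basis: BasisSpec
    ao_basis: AOBasis = field(repr=False)
    n_iterations: int = 0

    @property
    def nao(self) -> int:
        return self.ao_basis.nao

    def homo_energy(self) -> float:
        return float(self.orbital_energies[-1])


def _diis_extrapolate(fock_list, err_list):
    n = len(fock_list)
    B = -np.ones((n + 1, n + 1))
    B[n, n] = 0.0
    for i in range(n):
        for j in range(n):
            B[i, j] = np.vdot(err_list[i], err_list[j])
    rhs = np.zeros(n + 1)
    rhs[n] = -1.0
    try:
        c = np.linalg.solve(B, rhs)[:n]
    except np.linalg.LinAlgError:
        return fock_list[-1]
    return sum(ci * Fi for ci, Fi in zip(c, fock_list))


def run_rhf(
    mol: Molecule,
    basis,
    ghost_partner: Molecule | None = None,
    conv_energy: float = ENERGY_TOL,
    conv_drms: float = DRMS_TOL,
    max_iter: int = MAX_ITER,
    max_memory_gb: float = integrals.DEFAULT_MAX_MEMORY_GB,
) -> SCFResult:
    """Converge a restricted Hartree–Fock solution.

    Parameters
    ----------
    mol:
        Closed-shell molecule (even electron count).
    basis:
        Basis-set name or :class:`BasisSpec`.
    ghost_partner:
        Optional molecule whose centers carry basis functions only
        (counterpoise correction basis).
    """
    spec = _as_spec(basis)
    nelec = mol.n_electrons
    if nelec % 2 != 0:
        raise GeometryError(f"odd electron count {nelec}: not closed-shell")
    nocc = nelec // 2

    ao = basis_for_molecule(mol, spec, ghost_partner=ghost_partner)
    S, T = integrals.overlap_kinetic(ao)
    V = integrals.nuclear_attraction(ao)
    H = T + V
    Enuc = integrals.nuclear_repulsion(ao.charges, ao.charge_pos)

    # packed symmetric storage beyond ~100 AOs: 8x smaller, numba J/K build
    dense = ao.nao <= 100 and integrals.dense_memory_gb(ao.nao) <= max_memory_gb
    if dense:
        eri = integrals.eri_dense(ao, max_memory_gb)
        jk = lambda D: integrals.jk_dense(eri, D)
    else:
        eri = integrals.eri_packed(ao, max_memory_gb)
        jk = lambda D: integrals.jk_packed(eri, D)

    # symmetric orthogonalization with linear-dependence cutoff
    sval, svec = np.linalg.eigh(S)
    keep = sval > 1e-10
    X = svec[:, keep] / np.sqrt(sval[keep])

    def diagonalize(F):
        Fp = X.T @ F @ X
        e, Cp = np.linalg.eigh(Fp)
        return e, X @ Cp

    # extended-Hueckel-style (GWH) guess; much better start than bare H-core
    hdiag = np.diag(H)
    F0 = 0.875 * S * (hdiag[:, None] + hdiag[None, :])
    np.fill_diagonal(F0, hdiag)
    e, C = diagonalize(F0)
    Cocc = C[:, :nocc]
    P = Cocc @ Cocc.T

    history = []
    fock_list, err_list = [], []
    E_old = 0.0
    converged = False
    for it in range(1, max_iter + 1):
        J, K = jk(P)
        F = H + 2.0 * J - K
        E = float(np.sum(P * (H + F))) + Enuc

        err = F @ P @ S - S @ P @ F
        err = X.T @ err @ X
        fock_list.append(F)
        err_list.append(err)
        if len(fock_list) > 8:
            fock_list.pop(0)
            err_list.pop(0)
        if it > 1:
            F = _diis_extrapolate(fock_list, err_list)

        e, C = diagonalize(F)
        Cocc = C[:, :nocc]
        P_new = Cocc @ Cocc.T
        drms = float(np.sqrt(np.mean((P_new - P) ** 2)))
        dE = E - E_old
        history.append((it, E, dE, drms))
        P, E_old = P_new, E
        if it > 1 and abs(dE) < conv_energy and drms < conv_drms:
            converged = True
            break

    if not converged:
        raise SCFError(
            f"SCF did not converge in {max_iter} iterations "
            f"(last dE={history[-1][2]:.3e}, dRMS={history[-1][3]:.3e})",
            history=history,
        )

    # final consistent energies/orbitals
    J, K = jk(P)
    F = H + 2.0 * J - K
    e, C = diagonalize(F)
    Cocc = np.ascontiguousarray(C[:, :nocc])
    E = float(np.sum((Cocc @ Cocc.T) * (H + F))) + Enuc

    return SCFResult(
        mo_coefficients=Cocc,
        orbital_energies=e[:nocc].copy(),
        n_occupied=nocc,
        total_energy=E,
        converged=True,
        basis_mode="dimer_ghost" if ghost_partner is not None else "monomer",
        molecule=mol,
        basis=spec,
        ao_basis=ao,
        n_iterations=it,
    )
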