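"""Operator matrices and occupied-block integrals over a dimer AO basis.

The dimer AO basis is always ordered [fixed-monomer shells, mobile-monomer
shells].  Two ways of representing the monomer orbitals in that basis are
supported:

``monomer``
    Each monomer's SCF is solved in its own AO basis and embedded by
    zero-padding.  The basis-error term of the exchange decomposition is
    finite and reported.
``dimer_ghost``
    The fixed monomer's SCF is solved in the full dimer basis with the
    partner's centers as ghosts (counterpoise).  The mobile monomer's
    orbitals follow by translational symmetry (block swap), so only one
    SCF is required per arrangement.

The mobile monomer's orbitals are never recomputed independently: they are
the fixed monomer's coefficients attached to the translated centers, which
pins the relative phase of the two orbital sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import integrals
from .basis import AOBasis, BasisSpec, _as_spec, build_basis
from .geometry import DimerArrangement
from .scf import SCFResult, run_rhf
from .units import BOHR_PER_ANGSTROM

__all__ = [
    "OperatorMatrices",
    "OccERIBlock",
    "DimerBasis",
    "ContractError",
    "dimer_basis",
    "embed_coefficients",
    "operator_matrices",
    "occ_eri_block",
]


class ContractError(ValueError):
    """Inconsistent inputs (basis mismatch, dimension mismatch, ...)."""


@dataclass
class DimerBasis:
    """The dimer AO basis plus bookkeeping of the two monomer blocks."""

    arrangement: DimerArrangement
    basis: BasisSpec
    ao: AOBasis
    nao_monomer: int

    @property
    def nao(self) -> int:
        return self.ao.nao


def dimer_basis(dimer: DimerArrangement, basis) -> DimerBasis:
    spec = _as_spec(basis)
    fixed, mobile = dimer.fixed, dimer.mobile
    elements = list(fixed.elements) + list(mobile.elements)
    coords = np.vstack([fixed.coords, mobile.coords])
    ao = build_basis(elements, coords, spec)
    ao_f = build_basis(list(fixed.elements), fixed.coords, spec)
    return DimerBasis(dimer, spec, ao, ao_f.nao)


def embed_coefficients(db: DimerBasis, scf: SCFResult, which: str,
                       coefficients: np.ndarray | None = None) -> np.ndarray:
    """Occupied MO coefficients of one monomer over the dimer AO basis.

    ``which`` is "A" (fixed) or "B" (mobile).  For a monomer-basis SCF the
    coefficients are zero-padded into the corresponding block; for a
    counterpoise SCF of the fixed monomer the blocks are swapped to obtain
    the mobile monomer's orbitals (exact translated copy).  ``coefficients``
    overrides the raw SCF coefficients (e.g. symmetry-rotated ones).
    """
    n, nm = db.nao, db.nao_monomer
    C = scf.mo_coefficients if coefficients is None else coefficients
    out = np.zeros((n, scf.n_occupied))
    if scf.basis_mode == "monomer":
        if C.shape[0] != nm:
            raise ContractError(
                f"monomer SCF has {C.shape[0]} AOs, dimer block expects {nm}"
            )
        if which == "A":
            out[:nm] = C
        elif which == "B":
            out[nm:] = C
        else:
            raise ContractError(f"which must be 'A' or 'B', got {which!r}")
    elif scf.basis_mode == "dimer_ghost":
        if C.shape[0] != n:
            raise ContractError(
                f"ghost-basis SCF has {C.shape[0]} AOs, dimer basis has {n}"
            )
        if which == "A":
            out[:] = C
        elif which == "B":
            # The mobile monomer's counterpoise orbitals follow from the
            # fixed monomer's by reflecting through the molecular plane and
            # translating by +dz (a pure translation would carry the ghost
            # tail outside the dimer basis).  The reflection multiplies
            # each AO by (-1)^lz and exchanges real/ghost blocks; it relies
            # on the monomer's own z -> -z mirror symmetry (planar systems).
            zsign = (-1.0) ** db.ao.ao_l()[:nm, 2]
            out[:nm] = zsign[:, None] * C[nm:]
            out[nm:] = zsign[:, None] * C[:nm]
        else:
            raise ContractError(f"which must be 'A' or 'B', got {which!r}")
    else:
        raise ContractError(f"unknown basis_mode {scf.basis_mode!r}")
    return out


@dataclass
class OperatorMatrices:
    """One- and two-electron operator matrices over the dimer AO basis.

    J/K matrices are built from the spinless occupied densities
    P_X = C_X C_X^T of each monomer; the dimer Fock operator is
    F = T + v_A + 2J_A - K_A + v_B + 2J_B - K_B.
    """

    ao_overlap: np.ndarray
    kinetic: np.ndarray
    v_nuc_A: np.ndarray
    v_nuc_B: np.ndarray
    J_A: np.ndarray
    K_A: np.ndarray
    J_B: np.ndarray
    K_B: np.ndarray
    C_A: np.ndarray = field(repr=False, default=None)
    C_B: np.ndarray = field(repr=False, default=None)

    @property
    def pot_A(self) -> np.ndarray:
        """Effective one-electron potential of monomer A: v_A + 2J_A - K_A."""
        return self.v_nuc_A + 2.0 * self.J_A - self.K_A

    @property
    def pot_B(self) -> np.ndarray:
        return self.v_nuc_B + 2.0 * self.J_B - self.K_B

    @property
    def fock_A(self) -> np.ndarray:
        return self.kinetic + self.pot_A

    @property
    def fock_B(self) -> np.ndarray:
        return self.kinetic + self.pot_B

    @property
    def fock(self) -> np.ndarray:
        return self.kinetic + self.pot_A + self.pot_B


def _check_pair(scfA: SCFResult, scfB: SCFResult):
    if scfA.basis.key != scfB.basis.key:
        raise ContractError(
            f"basis mismatch: {scfA.basis.key} vs {scfB.basis.key}"
        )
    if scfA.basis_mode != scfB.basis_mode:
        raise ContractError(
            f"basis-mode mismatch: {scfA.basis_mode} vs {scfB.basis_mode}"
        )


def operator_matrices(
    dimer: DimerArrangement,
    scfA: SCFResult,
    scfB: SCFResult,
    basis,
    ao_eri: np.ndarray | None = None,
    C_A: np.ndarray | None = None,
    C_B: np.ndarray | None = None,
    max_memory_gb: float = integrals.DEFAULT_MAX_MEMORY_GB,
) -> OperatorMatrices:
    """All operator matrices of the dimer system.

    ``ao_eri`` may pass a precomputed dense AO ERI tensor of the dimer
    basis to avoid recomputation across operations; ``C_A``/``C_B`` may
    pass pre-embedded (possibly symmetry-rotated) occupied coefficients.
    """
    _check_pair(scfA, scfB)
    db = dimer_basis(dimer, basis)
    S, T = integrals.overlap_kinetic(db.ao)

    bohr = BOHR_PER_ANGSTROM
    za = dimer.fixed.atomic_numbers.astype(float)
    vA = integrals.nuclear_attraction(db.ao, za, dimer.fixed.coords * bohr)
    vB = integrals.nuclear_attraction(db.ao, za, dimer.mobile.coords * bohr)

    if C_A is None:
        C_A = embed_coefficients(db, scfA, "A")
    if C_B is None:
        C_B = embed_coefficients(db, scfB, "B")
    if ao_eri is None:
        ao_eri = integrals.eri_dense(db.ao, max_memory_gb)
    P_A = C_A @ C_A.T
    P_B = C_B @ C_B.T
    J_A, K_A = integrals.jk_dense(ao_eri, P_A)
    J_B, K_B = integrals.jk_dense(ao_eri, P_B)
    return OperatorMatrices(
        ao_overlap=S, kinetic=T, v_nuc_A=vA, v_nuc_B=vB,
        J_A=J_A, K_A=K_A, J_B=J_B, K_B=K_B, C_A=C_A, C_B=C_B,
    )


@dataclass
class OccERIBlock:
    """Occupied-only MO two-electron integrals in charge-density notation.

    ``g_abab[a, b, a2, b2] = (a b | a2 b2)`` with the first index of each
    charge density on monomer A and the second on B;
    ``g_aabb[a, a2, b, b2] = (a a2 | b b2)``.  All other index orders
    needed by the decomposition follow from permutational symmetry.
    """

    g_abab: np.ndarray
    g_aabb: np.ndarray

    def exchange_integral(self, a: int, b: int) -> float:
        """(ab|ba), the diagonal exchange integral of the pair."""
        return float(self.g_abab[a, b, a, b])


def occ_eri_block(
    scfA: SCFResult,
    scfB: SCFResult,
    basis,
    dimer: DimerArrangement,
    ao_eri: np.ndarray | None = None,
    C_A: np.ndarray | None = None,
    C_B: np.ndarray | None = None,
    max_memory_gb: float = integrals.DEFAULT_MAX_MEMORY_GB,
) -> OccERIBlock:
    """Transform dimer AO ERIs to the occupied MO blocks of both monomers."""
    _check_pair(scfA, scfB)
    db = dimer_basis(dimer, basis)
    if C_A is None:
        C_A = embed_coefficients(db, scfA, "A")
    if C_B is None:
        C_B = embed_coefficients(db, scfB, "B")
    if ao_eri is None:
        ao_eri = integrals.eri_dense(db.ao, max_memory_gb)

    # quarter transformations, most contracted index first
    # (mu nu|la si) -> (a nu|la si) -> (a b|la si) -> (a b|a2 si) -> (a b|a2 b2)
    t = np.tensordot(C_A, ao_eri, axes=(0, 0))          # a, nu, la, si
    t = np.tensordot(C_B, t, axes=(0, 1))               # b, a, la, si
    u = np.tensordot(C_A, t, axes=(0, 2))               # a2, b, a, si
    g_abab = np.tensordot(u, C_B, axes=(3, 0))          # a2, b, a, b2
    g_abab = np.ascontiguousarray(np.transpose(g_abab, (2, 1, 0, 3)))

    # (a a2 | b b2)
    t = np.tensordot(C_A, ao_eri, axes=(0, 0))          # a, nu, la, si
    t = np.tensordot(C_A, t, axes=(0, 1))               # a2, a, la, si
    u = np.tensordot(C_B, t, axes=(0, 2))               # b, a2, a, si
    g_aabb = np.tensordot(u, C_B, axes=(3, 0))          # b, a2, a, b2
    g_aabb = np.ascontiguousarray(np.transpose(g_aabb, (2, 1, 0, 3)))
    return OccERIBlock(g_abab=g_abab, g_aabb=g_aabb)
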