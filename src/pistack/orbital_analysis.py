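"""Symmetry classification of occupied monomer orbitals and cross overlaps.

Occupied MOs of a planar monomer (xy molecular plane, long axis x) are
classified as

* pi    -- antisymmetric under reflection through the molecular plane
           (z -> -z); sigma otherwise;
* S / A -- pi orbitals additionally symmetric / antisymmetric under the
           sigma_xz mirror (y -> -y).

The nS / nA designation ranks orbitals of each parity class by increasing
orbital energy; an nS or nA orbital has n - 1 nodal surfaces along the
long axis.  Degenerate sets (e.g. benzene e-type orbitals) come out of the
SCF in an arbitrary internal mixing, so degenerate blocks are rotated onto
symmetry eigenvectors before labels are assigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import integrals
from .basis import AOBasis, basis_for_molecule
from .estruct import ContractError, OperatorMatrices
from .geometry import Molecule, PlanarityError
from .scf import SCFResult

__all__ = [
    "LabeledOrbitals",
    "CrossOverlap",
    "ClassificationError",
    "classify_orbitals",
    "fix_phases",
    "cross_overlap",
    "count_pairs",
]

PURITY_THRESHOLD = 0.98
DEGENERACY_TOL = 1e-6


class ClassificationError(RuntimeError):
    """An orbital could not be assigned a definite symmetry label."""


@dataclass(frozen=True)
class OrbitalLabel:
    index: int              # energy order within the occupied space
    energy: float           # Hartree
    sigma_pi: str           # "pi" | "sigma"
    parity_xz: str | None   # "S" | "A" for pi orbitals, None for sigma
    class_rank: int | None  # n within (pi, S) or (pi, A)

    @property
    def name(self) -> str:
        if self.sigma_pi == "pi":
            return f"{self.class_rank}{self.parity_xz}"
        return f"sigma{self.index + 1}"


@dataclass
class LabeledOrbitals:
    """Classified occupied orbitals of one monomer.

    Holds its own coefficient matrix: degenerate blocks may have been
    rotated relative to the raw SCF solution (energies are unchanged).
    """

    scf: SCFResult
    mo_coefficients: np.ndarray
    orbital_energies: np.ndarray
    labels: tuple[OrbitalLabel, ...]
    degenerate_groups: tuple[tuple[int, ...], ...] = ()

    @property
    def n_occupied(self) -> int:
        return len(self.labels)

    @property
    def pi_indices(self) -> list[int]:
        return [l.index for l in self.labels if l.sigma_pi == "pi"]

    @property
    def sigma_indices(self) -> list[int]:
        return [l.index for l in self.labels if l.sigma_pi == "sigma"]

    def pi_by_parity(self, parity: str) -> list[int]:
        return [l.index for l in self.labels
                if l.sigma_pi == "pi" and l.parity_xz == parity]

    def index_of(self, name: str) -> int:
        """Occupied index of a label such as '6S', '5A' or 'sigma12'."""
        for l in self.labels:
            if l.name == name:
                return l.index
        raise KeyError(f"no occupied orbital labeled {name!r}")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [l.index for l in self.labels],
                "energy_hartree": [l.energy for l in self.labels],
                "class": [l.sigma_pi for l in self.labels],
                "parity_xz": [l.parity_xz or "" for l in self.labels],
                "rank": [l.class_rank if l.class_rank is not None else -1
                         for l in self.labels],
                "label": [l.name for l in self.labels],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _reflection_rep(ao: AOBasis, mol: Molecule, axis: int):
    """AO permutation + sign representation of a mirror flipping `axis`.

    Returns (perm, sign): AO mu of the reflected function equals
    sign[mu] * AO perm[mu] of the original set.
    """
    coords = mol.coords.copy()
    ref = coords.copy()
    ref[:, axis] = -ref[:, axis]
    # atom mapping under the reflection
    amap = np.full(mol.natom, -1, dtype=int)
    for i in range(mol.natom):
        d = np.linalg.norm(coords - ref[i], axis=1)
        j = int(np.argmin(d))
        if d[j] > 1e-3 or mol.elements[i] != mol.elements[j]:
            raise ClassificationError(
                f"molecule is not symmetric under reflection of axis {axis}: "
                f"atom {i} has no mirror partner"
            )
        amap[i] = j
    ao_atom = ao.ao_atom()
    ao_l = ao.ao_l()
    # first AO index per atom (shells are generated per atom in order)
    first = {}
    for mu in range(ao.nao):
        first.setdefault(int(ao_atom[mu]), mu)
    perm = np.zeros(ao.nao, dtype=int)
    sign = np.zeros(ao.nao)
    for mu in range(ao.nao):
        atom = int(ao_atom[mu])
        offset = mu - first[atom]
        nu = first[amap[atom]] + offset
        perm[mu] = nu
        sign[mu] = (-1.0) ** ao_l[mu, axis]
    return perm, sign


def _restrict(ao: AOBasis, nao_sub: int) -> AOBasis:
    """Prefix sub-basis containing the shells of the first `nao_sub` AOs."""
    keep = ao.shell_ao < nao_sub
    return AOBasis(
        shell_l=ao.shell_l[keep],
        shell_center=ao.shell_center[keep],
        shell_pstart=ao.shell_pstart[keep],
        shell_pcount=ao.shell_pcount[keep],
        shell_ao=ao.shell_ao[keep],
        prim_exp=ao.prim_exp,
        prim_coef=ao.prim_coef,
        shell_atom=ao.shell_atom[keep],
        nao=nao_sub,
    )


def _degenerate_groups(energies, tol=DEGENERACY_TOL):
    groups, cur = [], [0]
    for i in range(1, len(energies)):
        if energies[i] - energies[cur[-1]] < tol:
            cur.append(i)
        else:
            groups.append(tuple(cur))
            cur = [i]
    groups.append(tuple(cur))
    return tuple(groups)


def classify_orbitals(scf: SCFResult, mol: Molecule | None = None) -> LabeledOrbitals:
    """Assign pi/sigma and S/A labels to the occupied orbitals.

    The molecule must be planar in the canonical orientation.  Raises
    :class:`ClassificationError` if any orbital has mixed parity weight
    (symmetry-broken SCF or mis-oriented input).
    """
    if mol is None:
        mol = scf.molecule
    if not mol.is_planar():
        raise PlanarityError(mol.max_out_of_plane())
    ao = scf.ao_basis
    S_ao, _ = integrals.overlap_kinetic(ao)
    C_full = scf.mo_coefficients
    eps = scf.orbital_energies

    # Ghost centers (counterpoise basis) generally break both mirrors, so
    # parities are measured on the real-monomer AO block only; shells are
    # emitted per atom in order, hence that block is an index prefix.
    nreal = int(np.sum(ao.ao_atom() < mol.natom))
    sub_ao = _restrict(ao, nreal)
    S_sub = S_ao[:nreal, :nreal]

    perm_z, sign_z = _reflection_rep(sub_ao, mol, axis=2)
    perm_y, sign_y = _reflection_rep(sub_ao, mol, axis=1)

    def parities(C, perm, sign):
        Cs = C[:nreal]
        CR = sign[:, None] * Cs[perm, :]
        num = np.einsum("mi,mn,ni->i", Cs, S_sub, CR)
        den = np.einsum("mi,mn,ni->i", Cs, S_sub, Cs)
        return num / den

    def rotate(C, perm, sign, groups):
        C = C.copy()
        for grp in groups:
            if len(grp) < 2:
                continue
            idx = list(grp)
            Cs = C[:nreal][:, idx]
            CR = sign[:, None] * C[:nreal][perm][:, idx]
            M = 0.5 * (Cs.T @ S_sub @ CR + (Cs.T @ S_sub @ CR).T)
            _, vecs = np.linalg.eigh(M)
            C[:, idx] = C[:, idx] @ vecs
        return C

    groups = _degenerate_groups(eps)
    C = rotate(C_full, perm_z, sign_z, groups)
    pz = parities(C, perm_z, sign_z)

    # within blocks degenerate AND of equal z-parity, resolve the xz mirror
    sub = []
    for grp in groups:
        if len(grp) < 2:
            continue
        grp = list(grp)
        plus = [i for i in grp if pz[i] > 0]
        minus = [i for i in grp if pz[i] <= 0]
        sub.extend([tuple(plus), tuple(minus)])
    C = rotate(C, perm_y, sign_y, sub)
    pz = parities(C, perm_z, sign_z)
    py = parities(C, perm_y, sign_y)

    labels = []
    for i in range(scf.n_occupied):
        if pz[i] < -PURITY_THRESHOLD:
            kind = "pi"
        elif pz[i] > PURITY_THRESHOLD:
            kind = "sigma"
        else:
            raise ClassificationError(
                f"orbital {i} has mixed molecular-plane parity "
                f"<R_z> = {pz[i]:+.4f}; check planarity/orientation"
            )
        parity = None
        if kind == "pi":
            if py[i] > PURITY_THRESHOLD:
                parity = "S"
            elif py[i] < -PURITY_THRESHOLD:
                parity = "A"
            else:
                raise ClassificationError(
                    f"pi orbital {i} has mixed sigma_xz parity "
                    f"<R_y> = {py[i]:+.4f}"
                )
        labels.append((i, float(eps[i]), kind, parity))

    # rank pi orbitals by energy within parity class
    out_labels = []
    counters = {"S": 0, "A": 0}
    for (i, e, kind, parity) in labels:
        rank = None
        if kind == "pi":
            counters[parity] += 1
            rank = counters[parity]
        out_labels.append(OrbitalLabel(i, e, kind, parity, rank))

    return LabeledOrbitals(
        scf=scf,
        mo_coefficients=C,
        orbital_energies=eps.copy(),
        labels=tuple(out_labels),
        degenerate_groups=groups,
    )


def fix_phases(lab: LabeledOrbitals) -> LabeledOrbitals:
    """Scale each MO by +-1 so its largest-|coefficient| AO is positive.

    Deterministic under ties: the lowest AO index wins (np.argmax).
    Idempotent; leaves every squared/bilinear observable unchanged.
    """
    C = lab.mo_coefficients.copy()
    for i in range(C.shape[1]):
        mu = int(np.argmax(np.abs(C[:, i])))
        if C[mu, i] < 0:
            C[:, i] = -C[:, i]
    return replace(lab, mo_coefficients=C)


@dataclass
class CrossOverlap:
    """Inter-monomer occupied MO overlap matrix S_ab and its provenance."""

    matrix: np.ndarray          # (nocc_A, nocc_B)
    labels_A: LabeledOrbitals
    labels_B: LabeledOrbitals

    def value(self, name_a: str, name_b: str) -> float:
        return float(self.matrix[self.labels_A.index_of(name_a),
                                 self.labels_B.index_of(name_b)])


def cross_overlap(labA: LabeledOrbitals, labB: LabeledOrbitals,
                  ops) -> CrossOverlap:
    """S_ab = C_A^T S_AO C_B over occupied orbitals.

    ``ops`` is an :class:`OperatorMatrices` (its embedded coefficient
    matrices are used) or a raw dimer AO overlap matrix, in which case the
    coefficients must be passed pre-embedded via labA/labB monkey layers.
    """
    if isinstance(ops, OperatorMatrices):
        S_ao, C_A, C_B = ops.ao_overlap, ops.C_A, ops.C_B
    else:
        raise ContractError("cross_overlap requires OperatorMatrices")
    if C_A.shape[0] != S_ao.shape[0] or C_B.shape[0] != S_ao.shape[1]:
        raise ContractError("dimension mismatch between coefficients and overlap")
    return CrossOverlap(matrix=C_A.T @ S_ao @ C_B, labels_A=labA, labels_B=labB)


def count_pairs(labA: LabeledOrbitals, labB: LabeledOrbitals,
                class_filter: str = "all") -> int:
    """Number of occupied orbital pairs (a, b) passing a class filter.

    ``pi-sigma`` counts both (pi, sigma) and (sigma, pi) orderings.
    """
    na_pi, na_sig = len(labA.pi_indices), len(labA.sigma_indices)
    nb_pi, nb_sig = len(labB.pi_indices), len(labB.sigma_indices)
    if class_filter == "all":
        return (na_pi + na_sig) * (nb_pi + nb_sig)
    if class_filter in ("pi-pi", "pipi"):
        return na_pi * nb_pi
    if class_filter in ("pi-sigma", "pisigma"):
        return na_pi * nb_sig + na_sig * nb_pi
    if class_filter in ("sigma-sigma", "sigmasigma"):
        return na_sig * nb_sig
    raise ValueError(f"unknown class filter {class_filter!r}")
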