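"""High-level driver over the numba integral kernels.

Provides one-electron matrices, nuclear repulsion, and two-electron
integrals in either a dense 4-index tensor (small systems) or canonically
packed 1D storage (8-fold permutational symmetry, Schwarz-screened), with
a memory-estimate guard.
"""

from __future__ import annotations

import numpy as np

from . import _md
from .basis import AOBasis

__all__ = [
    "MemoryLimitError",
    "overlap",
    "kinetic",
    "overlap_kinetic",
    "nuclear_attraction",
    "nuclear_repulsion",
    "eri_dense",
    "eri_packed",
    "jk_packed",
    "jk_dense",
]

SCREEN_THRESH = 1e-12
DEFAULT_MAX_MEMORY_GB = 4.0


class MemoryLimitError(MemoryError):
    """Requested integral tensor would exceed the configured memory cap."""


def _shell_args(b: AOBasis):
    return (b.shell_l, b.shell_center, b.shell_pstart, b.shell_pcount,
            b.shell_ao, b.prim_exp, b.prim_coef, b.nao)


def overlap_kinetic(b: AOBasis):
    return _md.build_overlap_kinetic(*_shell_args(b))


def overlap(b: AOBasis) -> np.ndarray:
    return overlap_kinetic(b)[0]


def kinetic(b: AOBasis) -> np.ndarray:
    return overlap_kinetic(b)[1]


def nuclear_attraction(b: AOBasis, charges=None, positions=None) -> np.ndarray:
    """V_ne over the AO basis; default charges/positions are the basis' own
    non-ghost nuclei.  Positions in Bohr."""
    if charges is None:
        charges, positions = b.charges, b.charge_pos
    charges = np.asarray(charges, dtype=float)
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if len(charges) == 0:
        return np.zeros((b.nao, b.nao))
    return _md.build_nuclear(*_shell_args(b), charges, positions)


def nuclear_repulsion(charges, positions) -> float:
    """Point-charge repulsion energy; positions in Bohr."""
    charges = np.asarray(charges, dtype=float)
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    e = 0.0
    for i in range(len(charges)):
        for j in range(i):
            r = np.linalg.norm(positions[i] - positions[j])
            e += charges[i] * charges[j] / r
    return e


def dense_memory_gb(nao: int) -> float:
    return nao ** 4 * 8 / 1024 ** 3


def packed_memory_gb(nao: int) -> float:
    npair = nao * (nao + 1) // 2
    return npair * (npair + 1) // 2 * 8 / 1024 ** 3


def eri_dense(b: AOBasis, max_memory_gb: float = DEFAULT_MAX_MEMORY_GB):
    need = dense_memory_gb(b.nao)
    if need > max_memory_gb:
        raise MemoryLimitError(
            f"dense ERI tensor for {b.nao} AOs needs {need:.2f} GB "
            f"(cap {max_memory_gb:.2f} GB); use the packed path or a smaller basis"
        )
    return _md.build_eri_dense(*_shell_args(b), SCREEN_THRESH)


def eri_packed(b: AOBasis, max_memory_gb: float = DEFAULT_MAX_MEMORY_GB):
    need = packed_memory_gb(b.nao)
    if need > max_memory_gb:
        raise MemoryLimitError(
            f"packed ERI storage for {b.nao} AOs needs {need:.2f} GB "
            f"(cap {max_memory_gb:.2f} GB)"
        )
    return _md.build_eri_packed(*_shell_args(b), SCREEN_THRESH)


def jk_packed(eri: np.ndarray, D: np.ndarray):
    """J/K from packed ERIs and a symmetric spinless density matrix."""
    return _md.jk_from_packed(eri, np.ascontiguousarray(D), D.shape[0])


def jk_dense(eri: np.ndarray, D: np.ndarray):
    J = np.einsum("pqrs,rs->pq", eri, D, optimize=True)
    K = np.einsum("prqs,rs->pq", eri, D, optimize=True)
    return J, K
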