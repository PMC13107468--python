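"""Particle-in-a-box model for the overlap of slipped pi-systems.

Each monomer's pi-orbitals are approximated by 1D box eigenfunctions
psi_n(x) = sqrt(2/L) sin(pi n x / L) on [0, L]; the partner's box is
shifted by Delta.  With a = Delta / L the overlap between state n of one
box and m of the other has the closed form

    S_B(n,m; a) = (2/pi) [(-1)^(n+m) n sin(pi m a) - m sin(pi n a)] / (n^2 - m^2)   (n != m)
    S_B(n,n; a) = (1 - a) cos(pi n a) + sin(pi n a) / (n pi)

for 0 <= a <= 1 and exactly 0 for a >= 1 (disjoint boxes).  The box length
L corresponds to the spatial extension of the pi-system along the shift
direction; the module defaults mirror a linear pentacene-sized system
(15 A along the long axis) and its transverse extension (6.3 A).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["PIBSpec", "pib_overlap", "pib_sq_sum", "pib_mixed_sq_sum", "pib_curve",
           "DEFAULT_L_X", "DEFAULT_L_Y"]

DEFAULT_L_X = 15.0  # Angstrom, long-axis box
DEFAULT_L_Y = 6.3   # Angstrom, short-axis box


@dataclass(frozen=True)
class PIBSpec:
    """Box length L (Angstrom) and number of occupied model orbitals N."""

    L: float = DEFAULT_L_X
    N: int = 6

    def __post_init__(self):
        if not self.L > 0:
            raise ValueError("box length L must be positive")
        if not (isinstance(self.N, (int, np.integer)) and self.N >= 1):
            raise ValueError("N must be a positive integer")


def _pib_overlap_real(n: float, m: float, a: float) -> float:
    """Overlap formula with real-valued quantum numbers (continuity checks
    of the two branches); not part of the public contract."""
    if a >= 1.0:
        return 0.0
    if abs(n - m) < 1e-12:
        return (1.0 - a) * math.cos(math.pi * n * a) \
            + math.sin(math.pi * n * a) / (n * math.pi)
    # exact antiderivative form, continuous in real m (reduces to the
    # integer closed form when n - m is an integer)
    t1 = (math.sin((n - m) * math.pi + m * math.pi * a)
          - math.sin(n * math.pi * a)) / ((n - m) * math.pi)
    t2 = (math.sin((n + m) * math.pi - m * math.pi * a)
          - math.sin(n * math.pi * a)) / ((n + m) * math.pi)
    return t1 - t2


def pib_overlap(n: int, m: int, a: float) -> float:
    """Overlap S_B(n, m) of two box states at dimensionless shift a >= 0."""
    if not (isinstance(n, (int, np.integer)) and isinstance(m, (int, np.integer))):
        raise TypeError("quantum numbers must be integers")
    if n < 1 or m < 1:
        raise ValueError("quantum numbers must be >= 1")
    if a < 0:
        raise ValueError("shift a must be non-negative")
    if a >= 1.0:
        return 0.0
    if n == m:
        return (1.0 - a) * math.cos(math.pi * n * a) \
            + math.sin(math.pi * n * a) / (n * math.pi)
    return (2.0 / math.pi) \
        * ((-1.0) ** (n + m) * n * math.sin(math.pi * m * a)
           - m * math.sin(math.pi * n * a)) / (n * n - m * m)


def pib_sq_sum(N: int, a: float) -> float:
    """Sum of squared overlaps over all n, m <= N (the S_B^2_N sum)."""
    if N < 1:
        raise ValueError("N must be >= 1")
    return float(sum(pib_overlap(n, m, a) ** 2
                     for n in range(1, N + 1) for m in range(1, N + 1)))


def pib_mixed_sq_sum(N1: int, N2: int, a: float) -> float:
    """S_B^2_{N1} + S_B^2_{N2}: model analogue of a full pi set split into
    mirror-symmetric and antisymmetric subsets (e.g. 6 + 5)."""
    return pib_sq_sum(N1, a) + pib_sq_sum(N2, a)


def pib_curve(spec: PIBSpec, shifts, observable: str = "sq_sum",
              n: int | None = None, m: int | None = None):
    """Sampled model curve over shifts Delta (Angstrom).

    observable:
      * "overlap"  -- S_B(n, m) (requires n, m)
      * "sq"       -- S_B^2(n, m) (requires n, m)
      * "sq_sum"   -- S_B^2_N over all n, m <= N
      * "sq_sum_split" -- S_B^2_N + S_B^2_{N-1} (full split pi set)

    Returns a :class:`pistack.scan.ScanResult`.
    """
    from .scan import ScanResult

    shifts = np.asarray(shifts, dtype=float)
    if np.any(shifts < 0):
        raise ValueError("shifts must be non-negative")
    avals = shifts / spec.L
    if observable in ("overlap", "sq"):
        if n is None or m is None:
            raise ValueError(f"observable {observable!r} needs n and m")
        vals = np.array([pib_overlap(n, m, a) for a in avals])
        if observable == "sq":
            vals = vals ** 2
        name = f"S_B({n},{m})" if observable == "overlap" else f"S_B2({n},{m})"
    elif observable == "sq_sum":
        vals = np.array([pib_sq_sum(spec.N, a) for a in avals])
        name = f"S_B2_sum(N={spec.N})"
    elif observable == "sq_sum_split":
        vals = np.array([pib_mixed_sq_sum(spec.N, spec.N - 1, a)
                         for a in avals])
        name = f"S_B2_sum(N={spec.N}+{spec.N - 1})"
    else:
        raise ValueError(f"unknown observable {observable!r}")
    return ScanResult(
        axis="x",
        shifts=shifts,
        columns={name: vals},
        units={name: "dimensionless"},
        provenance={"model": "particle_in_a_box", "L": spec.L, "N": spec.N},
    )
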