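"""Built-in monomer geometries.

Small closed-shell systems for testing (He, H2, ethylene) and idealized
planar acene geometries (benzene ... pentacene) built from aromatic C-C
1.40 A, C-H 1.09 A and 120 degree angles.  The idealized acenes reproduce
every combinatorial/symmetry property of the optimized structures exactly
and overlap-curve feature positions approximately; externally optimized
coordinates can be substituted through :func:`pistack.geometry.read_xyz`
for quantitatively exact feature positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import DimerArrangement, Molecule, build_dimer, canonical_orient

__all__ = ["Fixture", "FixtureLookupError", "fixture", "acene", "available_fixtures"]

CC_AROMATIC = 1.40  # A
CH_BOND = 1.09      # A

_ACENE_RINGS = {
    "benzene": 1,
    "naphthalene": 2,
    "anthracene": 3,
    "tetracene": 4,
    "pentacene": 5,
}


class FixtureLookupError(KeyError):
    """Unknown fixture name."""


@dataclass(frozen=True)
class Fixture:
    """A named monomer plus the recommended basis and usage notes."""

    name: str
    molecule: Molecule
    recommended_basis: str
    default_dz: float
    notes: str

    def dimer(self, dx: float = 0.0, dy: float = 0.0,
              dz: float | None = None) -> DimerArrangement:
        return build_dimer(self.molecule, dx, dy,
                           self.default_dz if dz is None else dz)


def acene(n_rings: int) -> Molecule:
    """Idealized linear acene C_{4n+2}H_{2n+4} in the canonical orientation.

    Fused regular hexagons with shared vertical C-C bonds; long axis x,
    short axis y, molecule in the xy-plane.
    """
    if n_rings < 1:
        raise ValueError("need at least one ring")
    d = CC_AROMATIC
    hx = d * math.sqrt(3.0) / 2.0  # half the ring pitch along x
    ring_pitch = 2.0 * hx
    elements, coords = [], []
    # bridgehead carbons at ring boundaries
    x0 = -n_rings * hx
    for i in range(n_rings + 1):
        x = x0 + i * ring_pitch
        for s in (1.0, -1.0):
            elements.append("C")
            coords.append((x, s * d / 2.0, 0.0))
    # apex carbons above/below each ring center
    for k in range(n_rings):
        xc = x0 + hx + k * ring_pitch
        for s in (1.0, -1.0):
            elements.append("C")
            coords.append((xc, s * d, 0.0))
    # apex hydrogens
    for k in range(n_rings):
        xc = x0 + hx + k * ring_pitch
        for s in (1.0, -1.0):
            elements.append("H")
            coords.append((xc, s * (d + CH_BOND), 0.0))
    # terminal hydrogens on the four outermost bridgehead carbons
    c30, s30 = math.cos(math.pi / 6.0), math.sin(math.pi / 6.0)
    for xe, sx in ((x0, -1.0), (x0 + n_rings * ring_pitch, 1.0)):
        for s in (1.0, -1.0):
            elements.append("H")
            coords.append((xe + sx * CH_BOND * c30,
                           s * (d / 2.0 + CH_BOND * s30), 0.0))
    return canonical_orient(Molecule(tuple(elements), np.array(coords)))


def _ethylene() -> Molecule:
    # C=C 1.339 A, C-H 1.086 A, HCC 121.3 deg, planar in xy
    rcc, rch, ang = 1.339, 1.086, math.radians(121.3)
    xc = rcc / 2.0
    xh = xc + rch * abs(math.cos(ang))
    yh = rch * math.sin(ang)
    elements = ("C", "C", "H", "H", "H", "H")
    coords = np.array([
        (-xc, 0.0, 0.0), (xc, 0.0, 0.0),
        (-xh, yh, 0.0), (-xh, -yh, 0.0),
        (xh, yh, 0.0), (xh, -yh, 0.0),
    ])
    return canonical_orient(Molecule(elements, coords))


def _registry() -> dict[str, Fixture]:
    reg = {}
    reg["he2"] = Fixture(
        "he2",
        Molecule(("He",), np.zeros((1, 3))),
        "sto-3g", 3.0,
        "helium pair; the dimer() separation is configurable via dz",
    )
    h2 = canonical_orient(
        Molecule(("H", "H"), np.array([(-0.37, 0.0, 0.0), (0.37, 0.0, 0.0)])),
        require_planar=False,
    )
    reg["h2_dimer"] = Fixture(
        "h2_dimer", h2, "sto-3g", 3.4,
        "cofacially stacked hydrogen molecules, bond along x",
    )
    reg["ethylene_dimer"] = Fixture(
        "ethylene_dimer", _ethylene(), "sto-3g", 3.4,
        "smallest pi-system; one occupied pi orbital",
    )
    for name, n in _ACENE_RINGS.items():
        reg[name] = Fixture(
            name, acene(n), "6-31g", 3.4,
            f"idealized planar {name} (C-C {CC_AROMATIC} A, C-H {CH_BOND} A); "
            "substitute optimized coordinates for quantitatively exact "
            "overlap-feature positions",
        )
    return reg


def available_fixtures() -> list[str]:
    return sorted(_registry())


def fixture(name: str) -> Fixture:
    """Look up a built-in monomer fixture by name."""
    reg = _registry()
    if name not in reg:
        raise FixtureLookupError(
            f"unknown fixture {name!r}; available: {sorted(reg)}"
        )
    return reg[name]


def reference_sapt_table_path() -> str:
    """Path of the shipped externally-computed SAPT0 component table."""
    import importlib.resources as ir

    return str(ir.files("pistack").joinpath("data/reference_sapt0_acenes.csv"))
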