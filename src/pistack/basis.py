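"""Gaussian basis sets and the AO basis built over a set of centers.

The shipped basis sets (STO-3G, 3-21G, 6-31G) are the standard published
parameter tables, stored inline.  Shells are expanded into flat arrays so
the numba integral kernels can iterate over them; all centers are stored
in Bohr.  Contracted coefficients include primitive normalization and a
final contracted normalization of the (l,0,0) Cartesian component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import BOHR_PER_ANGSTROM

__all__ = ["BasisSpec", "BasisSetError", "AOBasis", "build_basis", "available_basis_sets"]


class BasisSetError(ValueError):
    """Unknown basis name or unsupported basis configuration."""


# name -> element -> list of ("S"|"P"|"SP", [(exp, coef) or (exp, cs, cp)])
_BASIS_LIBRARY: dict[str, dict[str, list]] = {
    "sto-3g": {
        "H": [("S", [(3.42525091, 0.15432897), (0.62391373, 0.53532814),
                     (0.16885540, 0.44463454)])],
        "He": [("S", [(6.36242139, 0.15432897), (1.15892300, 0.53532814),
                      (0.31364979, 0.44463454)])],
        "C": [("S", [(71.6168370, 0.15432897), (13.0450960, 0.53532814),
                     (3.53051220, 0.44463454)]),
              ("SP", [(2.94124940, -0.09996723, 0.15591627),
                      (0.68348310, 0.39951283, 0.60768372),
                      (0.22228990, 0.70011547, 0.39195739)])],
        "N": [("S", [(99.1061690, 0.15432897), (18.0523120, 0.53532814),
                     (4.88566020, 0.44463454)]),
              ("SP", [(3.78045590, -0.09996723, 0.15591627),
                      (0.87849660, 0.39951283, 0.60768372),
                      (0.28571440, 0.70011547, 0.39195739)])],
        "O": [("S", [(130.7093200, 0.15432897), (23.8088610, 0.53532814),
                     (6.44360830, 0.44463454)]),
              ("SP", [(5.03315130, -0.09996723, 0.15591627),
                      (1.16959610, 0.39951283, 0.60768372),
                      (0.38038900, 0.70011547, 0.39195739)])],
    },
    "3-21g": {
        "H": [("S", [(5.4471780, 0.1562850), (0.8245470, 0.9046910)]),
              ("S", [(0.1831920, 1.0)])],
        "He": [("S", [(13.6267000, 0.1752300), (1.9993500, 0.8934830)]),
               ("S", [(0.3829930, 1.0)])],
        "C": [("S", [(172.2560000, 0.0617669), (25.9109000, 0.3587940),
                     (5.5333500, 0.7007130)]),
              ("SP", [(3.6649800, -0.3958970, 0.2364600),
                      (0.7705450, 1.2158400, 0.8606190)]),
              ("SP", [(0.1958570, 1.0, 1.0)])],
    },
    "6-31g": {
        "H": [("S", [(18.7311370, 0.03349460), (2.8253937, 0.23472695),
                     (0.6401217, 0.81375733)]),
              ("S", [(0.1612778, 1.0)])],
        "C": [("S", [(3047.5249000, 0.0018347), (457.3695100, 0.0140373),
                     (103.9486900, 0.0688426), (29.2101550, 0.2321844),
                     (9.2866630, 0.4679413), (3.1639270, 0.3623120)]),
              ("SP", [(7.8682724, -0.1193324, 0.0689991),
                      (1.8812885, -0.1608542, 0.3164240),
                      (0.5442493, 1.1434564, 0.7443083)]),
              ("SP", [(0.1687144, 1.0, 1.0)])],
    },
}


def available_basis_sets() -> list[str]:
    return sorted(_BASIS_LIBRARY)


@dataclass(frozen=True)
class BasisSpec:
    """Basis-set request: a resolvable name plus the density-fitting toggle."""

    name: str = "3-21g"
    density_fitting: bool = False
    aux_name: str | None = None

    def __post_init__(self):
        if self.name.lower() not in _BASIS_LIBRARY:
            raise BasisSetError(
                f"unknown basis set {self.name!r}; available: {available_basis_sets()}"
            )
        if self.density_fitting:
            raise BasisSetError(
                "density fitting is not supported by the built-in integral "
                "engine; conventional integrals with Schwarz screening are used"
            )
        if self.aux_name is not None and not self.density_fitting:
            raise BasisSetError("aux_name given but density_fitting is off")

    @property
    def key(self) -> str:
        return self.name.lower()


def _as_spec(basis) -> BasisSpec:
    if isinstance(basis, BasisSpec):
        return basis
    return BasisSpec(name=str(basis))


_DFACT = {0: 1.0, 1: 1.0, 2: 3.0, 3: 15.0, 4: 105.0}
_L_OF = {"S": 0, "P": 1, "D": 2, "F": 3}


@dataclass
class AOBasis:
    """Flat shell arrays over a set of centers (Bohr), numba-kernel ready."""

    shell_l: np.ndarray        # int64 (nsh,)
    shell_center: np.ndarray   # float64 (nsh, 3), Bohr
    shell_pstart: np.ndarray   # int64 (nsh,)
    shell_pcount: np.ndarray   # int64 (nsh,)
    shell_ao: np.ndarray       # int64 (nsh,), first AO index
    prim_exp: np.ndarray       # float64 (nprim,)
    prim_coef: np.ndarray      # float64 (nprim,), fully normalized
    shell_atom: np.ndarray     # int64 (nsh,), owning center index
    nao: int
    # point charges for the nuclear-attraction operator / nuclear repulsion;
    # ghost centers carry basis functions but no charge
    charges: np.ndarray = field(default_factory=lambda: np.zeros(0))
    charge_pos: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))

    @property
    def nshell(self) -> int:
        return len(self.shell_l)

    def ao_l(self) -> np.ndarray:
        """Per-AO angular momentum (lx, ly, lz) table, shape (nao, 3)."""
        out = np.zeros((self.nao, 3), dtype=int)
        for ish in range(self.nshell):
            l = int(self.shell_l[ish])
            k = int(self.shell_ao[ish])
            for lx in range(l, -1, -1):
                for ly in range(l - lx, -1, -1):
                    out[k] = (lx, ly, l - lx - ly)
                    k += 1
        return out

    def ao_atom(self) -> np.ndarray:
        """Owning center index per AO."""
        out = np.zeros(self.nao, dtype=int)
        for ish in range(self.nshell):
            l = int(self.shell_l[ish])
            n = (l + 1) * (l + 2) // 2
            out[self.shell_ao[ish]: self.shell_ao[ish] + n] = self.shell_atom[ish]
        return out


def _shell_raw(element: str, basis_key: str):
    lib = _BASIS_LIBRARY[basis_key]
    if element not in lib:
        raise BasisSetError(
            f"basis set {basis_key!r} has no parameters for element {element!r}"
        )
    out = []
    for kind, prims in lib[element]:
        if kind == "SP":
            out.append((0, [(e, cs) for (e, cs, _cp) in prims]))
            out.append((1, [(e, cp) for (e, _cs, cp) in prims]))
        else:
            out.append((_L_OF[kind], list(prims)))
    return out


def _normalize(l: int, prims):
    """Primitive + contracted normalization for the (l,0,0) component."""
    exps = np.array([p[0] for p in prims])
    coefs = np.array([p[1] for p in prims])
    norms = (2.0 * exps / np.pi) ** 0.75 * (4.0 * exps) ** (l / 2.0) / np.sqrt(_DFACT[l])
    c = coefs * norms
    ps = exps[:, None] + exps[None, :]
    self_ovl = ((np.pi / ps) ** 1.5 * _DFACT[l] / (2.0 * ps) ** l * np.outer(c, c)).sum()
    return exps, c / np.sqrt(self_ovl)


def build_basis(elements, coords_angstrom, basis, ghost_mask=None,
                charges=None) -> AOBasis:
    """Expand a basis over atomic centers.

    ``ghost_mask[i]`` True marks a center contributing basis functions but
    no nuclear charge or electrons (counterpoise partner).
    """
    spec = _as_spec(basis)
    coords = np.atleast_2d(np.asarray(coords_angstrom, dtype=float)) * BOHR_PER_ANGSTROM
    n = len(elements)
    if ghost_mask is None:
        ghost_mask = [False] * n
    from .geometry import ATOMIC_NUMBERS

    if charges is None:
        charges = [0 if ghost_mask[i] else ATOMIC_NUMBERS[elements[i]]
                   for i in range(n)]

    sl, sc, sp_, spc, sao, satom = [], [], [], [], [], []
    pexp, pcoef = [], []
    nao = 0
    for i, el in enumerate(elements):
        for l, prims in _shell_raw(el, spec.key):
            exps, cs = _normalize(l, prims)
            sl.append(l)
            sc.append(coords[i])
            sp_.append(len(pexp))
            spc.append(len(exps))
            sao.append(nao)
            satom.append(i)
            pexp.extend(exps)
            pcoef.extend(cs)
            nao += (l + 1) * (l + 2) // 2
    keep = [i for i in range(n) if charges[i] != 0]
    return AOBasis(
        shell_l=np.array(sl, dtype=np.int64),
        shell_center=np.array(sc, dtype=np.float64),
        shell_pstart=np.array(sp_, dtype=np.int64),
        shell_pcount=np.array(spc, dtype=np.int64),
        shell_ao=np.array(sao, dtype=np.int64),
        prim_exp=np.array(pexp, dtype=np.float64),
        prim_coef=np.array(pcoef, dtype=np.float64),
        shell_atom=np.array(satom, dtype=np.int64),
        nao=nao,
        charges=np.array([float(charges[i]) for i in keep]),
        charge_pos=coords[keep] if keep else np.zeros((0, 3)),
    )


def basis_for_molecule(mol, basis, ghost_partner=None) -> AOBasis:
    """AO basis of a molecule, optionally augmented with ghost centers."""
    elements = list(mol.elements)
    coords = mol.coords
    ghost = [False] * mol.natom
    if ghost_partner is not None:
        elements += list(ghost_partner.elements)
        coords = np.vstack([coords, ghost_partner.coords])
        ghost += [True] * ghost_partner.natom
    return build_basis(elements, coords, basis, ghost_mask=ghost)
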