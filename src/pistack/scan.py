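"""Scans of overlap/exchange observables over slip-stack displacement grids.

A scan reuses one monomer SCF for every grid point in monomer mode (the
mobile monomer is an exact translated copy, so only the inter-monomer AO
integrals change along the scan).  Features of the sampled curves --
zero crossings and local extrema -- are located on the grid and refined
with a local 3-point quadratic, matching the typical 0.1 A scan step.

Externally computed SAPT component-energy tables (electrostatic,
induction, dispersion, exchange) can be ingested from CSV for comparison
with the exchange decomposition.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import integrals
from .estruct import dimer_basis, embed_coefficients
from .geometry import DimerArrangement, Molecule, ScanGrid, make_grid
from .orbital_analysis import LabeledOrbitals, classify_orbitals, fix_phases
from .scf import SCFResult, run_rhf
from .units import HARTREE_TO_KJMOL

__all__ = [
    "ScanResult",
    "FeatureReport",
    "SAPTComponents",
    "SAPTValidationError",
    "run_scan",
    "find_features",
    "ingest_sapt_table",
]


@dataclass
class ScanResult:
    """Sampled observable curves over a displacement grid."""

    axis: str
    shifts: np.ndarray                  # Angstrom, strictly increasing
    columns: dict[str, np.ndarray]
    units: dict[str, str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.shifts = np.asarray(self.shifts, dtype=float)
        if len(self.shifts) > 1 and not np.all(np.diff(self.shifts) > 0):
            raise ValueError("shifts must be strictly increasing")
        for k, v in self.columns.items():
            v = np.asarray(v, dtype=float)
            if v.shape != self.shifts.shape:
                raise ValueError(f"column {k!r} length mismatch")
            self.columns[k] = v

    def column(self, name: str) -> np.ndarray:
        return self.columns[name]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"shift_angstrom": self.shifts})
        for k, v in self.columns.items():
            df[k] = v
        return df

    def to_csv(self, path) -> None:
        buf = io.StringIO()
        for k, u in self.units.items():
            buf.write(f"# {k} [{u}]\n")
        for k, v in self.provenance.items():
            buf.write(f"# {k}: {v}\n")
        self.to_dataframe().to_csv(buf, index=False)
        with open(path, "w") as fh:
            fh.write(buf.getvalue())


@dataclass(frozen=True)
class Feature:
    kind: str        # "zero" | "minimum" | "maximum"
    position: float  # Angstrom, refined, reported to 0.01 A
    value: float


@dataclass
class FeatureReport:
    """Zeros and local extrema of one scanned curve."""

    observable: str
    zeros: list[Feature]
    minima: list[Feature]
    maxima: list[Feature]
    refinement: str = "3-point quadratic"

    @property
    def all_features(self) -> list[Feature]:
        return sorted(self.zeros + self.minima + self.maxima,
                      key=lambda f: f.position)


def _quad_vertex(x, y):
    """Vertex of the parabola through three points; falls back to the
    middle point for degenerate (collinear) data."""
    denom = (x[0] - x[1]) * (x[0] - x[2]) * (x[1] - x[2])
    a = (x[2] * (y[1] - y[0]) + x[1] * (y[0] - y[2]) + x[0] * (y[2] - y[1])) / denom
    b = (x[2] ** 2 * (y[0] - y[1]) + x[1] ** 2 * (y[2] - y[0])
         + x[0] ** 2 * (y[1] - y[2])) / denom
    c = (x[1] * x[2] * (x[1] - x[2]) * y[0] + x[2] * x[0] * (x[2] - x[0]) * y[1]
         + x[0] * x[1] * (x[0] - x[1]) * y[2]) / denom
    if abs(a) < 1e-300:
        return x[1], y[1]
    xv = -b / (2 * a)
    return xv, a * xv ** 2 + b * xv + c


def _quad_root(x, y, lo, hi):
    """Root of the parabola through three points inside [lo, hi]; falls
    back to linear interpolation between the bracketing points."""
    denom = (x[0] - x[1]) * (x[0] - x[2]) * (x[1] - x[2])
    a = (x[2] * (y[1] - y[0]) + x[1] * (y[0] - y[2]) + x[0] * (y[2] - y[1])) / denom
    b = (x[2] ** 2 * (y[0] - y[1]) + x[1] ** 2 * (y[2] - y[0])
         + x[0] ** 2 * (y[1] - y[2])) / denom
    c = (x[1] * x[2] * (x[1] - x[2]) * y[0] + x[2] * x[0] * (x[2] - x[0]) * y[1]
         + x[0] * x[1] * (x[0] - x[1]) * y[2]) / denom
    roots = []
    if abs(a) > 1e-300:
        disc = b * b - 4 * a * c
        if disc >= 0:
            for s in (+1, -1):
                roots.append((-b + s * np.sqrt(disc)) / (2 * a))
    elif abs(b) > 1e-300:
        roots.append(-c / b)
    roots = [r for r in roots if lo - 1e-12 <= r <= hi + 1e-12]
    if roots:
        return float(min(roots, key=lambda r: abs(r - 0.5 * (lo + hi))))
    return None


def find_features(shifts, values, observable: str = "",
                  zero_tol: float = 0.0) -> FeatureReport:
    """Zeros (sign changes) and interior extrema of a sampled curve.

    Positions are refined with a 3-point quadratic and reported rounded
    to 0.01 A; each refined position lies within one grid step of its
    bracketing points.
    """
    x = np.asarray(shifts, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points for feature detection")
    zeros, minima, maxima = [], [], []
    n = len(x)
    for i in range(n - 1):
        if y[i] == 0.0 and (i == 0 or y[i - 1] != 0.0):
            zeros.append(Feature("zero", round(float(x[i]), 2), 0.0))
            continue
        if y[i] * y[i + 1] < 0:
            k = max(0, min(i - 1, n - 3))
            xr = _quad_root(x[k:k + 3], y[k:k + 3], x[i], x[i + 1])
            if xr is None:
                xr = x[i] - y[i] * (x[i + 1] - x[i]) / (y[i + 1] - y[i])
            zeros.append(Feature("zero", round(float(xr), 2), 0.0))
    for i in range(1, n - 1):
        if y[i] < y[i - 1] and y[i] <= y[i + 1]:
            xv, yv = _quad_vertex(x[i - 1:i + 2], y[i - 1:i + 2])
            xv = min(max(xv, x[i - 1]), x[i + 1])
            minima.append(Feature("minimum", round(float(xv), 2), float(yv)))
        elif y[i] > y[i - 1] and y[i] >= y[i + 1]:
            xv, yv = _quad_vertex(x[i - 1:i + 2], y[i - 1:i + 2])
            xv = min(max(xv, x[i - 1]), x[i + 1])
            maxima.append(Feature("maximum", round(float(xv), 2), float(yv)))
    return FeatureReport(observable=observable, zeros=zeros,
                         minima=minima, maxima=maxima)


def _overlap_observables(observables):
    """Split observable names into overlap-pair and group requests."""
    pairs, groups, need_mopce = [], [], []
    for name in observables:
        if name.startswith("S(") and name.endswith(")"):
            a, b = name[2:-1].split(",")
            pairs.append((name, a.strip(), b.strip()))
        elif name.startswith("S2(") and name.endswith(")"):
            groups.append(name)
        elif name.startswith("Exr"):
            need_mopce.append(name)
        else:
            raise ValueError(f"unknown observable {name!r}")
    return pairs, groups, need_mopce


def run_scan(
    mol: Molecule,
    grid: ScanGrid,
    observables,
    basis="3-21g",
    mode: str = "monomer",
    monomer_scf: SCFResult | None = None,
    labels: LabeledOrbitals | None = None,
    max_memory_gb: float = integrals.DEFAULT_MAX_MEMORY_GB,
) -> ScanResult:
    """Evaluate observables at every grid point.

    Overlap observables: ``"S(6S,6S)"`` (a single inter-monomer MO overlap
    by label), ``"S2(pi-pi)"``, ``"S2(piS-piS)"``, ``"S2(piA-piA)"``,
    ``"S2(piS-piA)"``, ``"S2(all)"`` (grouped squared-overlap sums).
    Exchange observables (``"Exr"``, ``"Exr(pi-pi)"``, ``"Exr(pi-sigma)"``,
    ``"Exr(sigma-sigma)"``, ``"Exr(piS-piS)"``, ``"Exr(piA-piA)"``,
    ``"Exr(piS-piA)"``) evaluate the full pair decomposition per point
    (expensive; small systems only).

    The monomer SCF is computed once and reused; in ``dimer_ghost`` mode
    every exchange-decomposition point recomputes the counterpoise SCF.
    Failed points are recorded as NaN and listed in provenance.
    """
    from .mopce import MopceContext, group_sums, pair_table, squared_overlap_sums

    pairs, groups, mopce_cols = _overlap_observables(observables)
    if monomer_scf is None:
        monomer_scf = run_rhf(mol, basis, max_memory_gb=max_memory_gb)
    if labels is None:
        labels = fix_phases(classify_orbitals(monomer_scf))

    arrangements = make_grid(mol, grid)
    shifts = grid.points
    cols = {name: np.full(len(shifts), np.nan)
            for name in [p[0] for p in pairs] + groups + mopce_cols}
    failed = []
    for i, arr in enumerate(arrangements):
        try:
            if pairs or groups:
                db = dimer_basis(arr, monomer_scf.basis)
                S_ao, _ = integrals.overlap_kinetic(db.ao)
                C_A = embed_coefficients(db, monomer_scf, "A",
                                         coefficients=labels.mo_coefficients)
                C_B = embed_coefficients(db, monomer_scf, "B",
                                         coefficients=labels.mo_coefficients)
                S = C_A.T @ S_ao @ C_B
                for (name, la, lb) in pairs:
                    cols[name][i] = S[labels.index_of(la), labels.index_of(lb)]
                if groups:
                    from .orbital_analysis import CrossOverlap
                    xs = CrossOverlap(S, labels, labels)
                    gr = squared_overlap_sums(xs)
                    for name in groups:
                        cols[name][i] = gr[name]
            if mopce_cols:
                ctx = MopceContext.build(monomer_scf, arr, mode=mode,
                                         labels=labels,
                                         max_memory_gb=max_memory_gb)
                tab = pair_table(ctx)
                ge = group_sums(tab)
                kj = ge.as_kjmol()
                alias = {"Exr": "E_xr",
                         "Exr(pi-pi)": "E_xr(pi-pi)",
                         "Exr(pi-sigma)": "E_xr(pi-sigma)",
                         "Exr(sigma-sigma)": "E_xr(sigma-sigma)",
                         "Exr(piS-piS)": "E_xr(piS-piS)",
                         "Exr(piA-piA)": "E_xr(piA-piA)",
                         "Exr(piS-piA)": "E_xr(piS-piA)"}
                for name in mopce_cols:
                    cols[name][i] = kj[alias[name]]
        except Exception as exc:  # pragma: no cover - defensive path
            failed.append((i, float(shifts[i]), repr(exc)))
            warnings.warn(f"scan point {i} (shift {shifts[i]:.2f} A) failed: {exc}")
    units = {}
    for name in cols:
        units[name] = "kJ/mol" if name.startswith("Exr") else "dimensionless"
    prov = {
        "basis": monomer_scf.basis.key,
        "mode": mode,
        "axis": grid.axis,
        "dz": grid.dz,
        "n_failed": len(failed),
    }
    if grid.axis == "x_at_fixed_y":
        prov["fixed_dy"] = grid.fixed_dy
    if failed:
        prov["failed_points"] = failed
    return ScanResult(axis=grid.axis, shifts=shifts, columns=cols,
                      units=units, provenance=prov)


@dataclass(frozen=True)
class SAPTComponents:
    """One ingested SAPT record (kJ/mol): E_int = E_el + E_ind + E_dsp + E_exch."""

    dx: float
    dy: float
    e_int: float
    e_el: float
    e_ind: float
    e_dsp: float
    e_exch: float
    system: str = ""

    @property
    def additivity_residual(self) -> float:
        return self.e_int - (self.e_el + self.e_ind + self.e_dsp + self.e_exch)


class SAPTValidationError(ValueError):
    """Ingested SAPT rows violate the component additivity."""


_SAPT_ALIASES = {
    "e_int": ("e_int", "eint", "int"),
    "e_el": ("e_el", "eel", "el", "e_elst", "elst"),
    "e_ind": ("e_ind", "eind", "ind"),
    "e_dsp": ("e_dsp", "edsp", "dsp", "e_disp", "disp"),
    "e_exch": ("e_exch", "eexch", "exch"),
}


def ingest_sapt_table(path, additivity_tol: float = 0.01) -> list[SAPTComponents]:
    """Read a CSV of externally computed SAPT component energies (kJ/mol).

    Required columns (case-insensitive, common aliases accepted):
    E_int, E_el, E_ind, E_dsp, E_exch; optional dx, dy, system.
    Rows whose components do not sum to E_int within ``additivity_tol``
    kJ/mol raise :class:`SAPTValidationError` listing the offenders.
    """
    df = pd.read_csv(path, comment="#")
    if df.empty:
        warnings.warn(f"SAPT table {path} contains no rows")
        return []
    colmap = {}
    lower = {c.lower().strip(): c for c in df.columns}
    for key, aliases in _SAPT_ALIASES.items():
        for al in aliases:
            if al in lower:
                colmap[key] = lower[al]
                break
        else:
            raise SAPTValidationError(f"missing required column {key}")
    records, bad = [], []
    for idx, row in df.iterrows():
        rec = SAPTComponents(
            dx=float(row[lower["dx"]]) if "dx" in lower else np.nan,
            dy=float(row[lower["dy"]]) if "dy" in lower else np.nan,
            e_int=float(row[colmap["e_int"]]),
            e_el=float(row[colmap["e_el"]]),
            e_ind=float(row[colmap["e_ind"]]),
            e_dsp=float(row[colmap["e_dsp"]]),
            e_exch=float(row[colmap["e_exch"]]),
            system=str(row[lower["system"]]) if "system" in lower else "",
        )
        if abs(rec.additivity_residual) > additivity_tol + 1e-9:
            bad.append((int(idx), rec.additivity_residual))
        records.append(rec)
    if bad:
        raise SAPTValidationError(
            "component sums deviate from E_int beyond "
            f"{additivity_tol} kJ/mol in rows: {bad}"
        )
    return records
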