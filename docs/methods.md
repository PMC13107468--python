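# Methods

## Model

`pistack` analyzes dimers of one planar closed-shell monomer and an
exact translated copy of it. The fixed monomer lies in the xy-plane with
its long axis along x (canonical orientation); the mobile copy is
displaced by (Δx, Δy, Δz) with Δz > 0 held fixed along a scan — the
standard slip-stacked geometry of π-aggregates, with Δz = 3.4 Å as the
default typical inter-planar distance.

The quantity of interest is the first-order exchange (Pauli) repulsion
between the two monomers' Hartree–Fock determinants, partitioned into
occupied orbital-pair contributions:

    E_xr       = Σ_ab E_xr(a,b)
    E_xr(a,b)  = E_xi(a,b) + E_xr2(a,b) + E_xr3(a,b) + E_xr4(a,b) + E_xrb(a,b)

with (all orbitals occupied, real; S_ab = ⟨a|b⟩; 𝒱_X = V̂_X + 2Ĵ_X − K̂_X
the effective potential of monomer X; F̂_X = T̂ + 𝒱_X; F̂ = T̂ + 𝒱_A + 𝒱_B):

    E_xi  = −2(ab|ba)
    E_xr2 = −2 S_ab [ (b|𝒱_A|a) + (a|𝒱_B|b) ]
    E_xr3 =  2 S_ab [ Σ_a′ (a|𝒱_B|a′) S_a′b + Σ_b′ (b|𝒱_A|b′) S_b′a ]
    E_xr4 =  2 S_ab Σ_a′b′ [ 4(ab|a′b′) − (ab′|a′b) − (aa′|bb′) ] S_a′b′
    E_xrb =  2 S_ab [ −(a|F̂_A|b) + Σ_a′ (a|F̂_A|a′) S_a′b
                      −(b|F̂_B|a) + Σ_b′ (b|F̂_B|b′) S_b′a ]

This decomposition sums *identically* (to machine precision, pair by
pair) to the defining single expression in terms of the dimer Fock
operator; the test suite asserts the identity at 1e-12 Hartree. For
orbitals canonical in the basis at hand, the two-index term has the
equivalent eigenvalue form

    E_xr2 = −2 (ε_a + ε_b) S_ab² + 4 S_ab T_ab ,

which the implementation evaluates alongside the potential form as a
diagnostic. Two remarks on equation forms:

* The eigenvalue form carries the kinetic cross term with coefficient
  **4**, not 2: substituting F̂_X ψ = ε ψ into either the defining
  expression or the potential form yields +4 S_ab T_ab, and only with
  that coefficient do the two forms agree (verified symbolically and
  numerically). 
* The difference between the two E_xr2 forms equals E_xrb exactly. In
  the monomer-embedded basis (see below) E_xrb is the finite-basis
  error and the difference is therefore *not* small for small basis
  sets; in the counterpoise basis both E_xrb and the difference vanish
  identically (asserted at 1e-7 Hartree). The package stores the
  potential form, which keeps the component-sum identity exact in every
  mode.

The pair attribution of the three- and four-index terms follows the
grouping written above (the outer S_ab factor defines the pair); no
alternative attributions are offered, since many-index terms admit no
unique pair split.

## Basis modes

Two representations of the monomer orbitals over the dimer AO basis
(always ordered [fixed shells, mobile shells]):

* `monomer` (default): each monomer solved in its own AO basis and
  zero-padded. E_xrb is finite and reported. The mobile monomer's
  coefficients are the fixed monomer's attached to the translated
  centers — never an independent SCF — which pins the relative phase of
  the two orbital sets and makes the sign of S_ab well defined.
* `dimer_ghost`: the fixed monomer solved with the partner's centers as
  ghost functions (counterpoise). The mobile monomer's orbitals follow
  by symmetry: reflection through the molecular plane (AO factor
  (−1)^lz, exchanging real and ghost blocks) followed by translation.
  A naive block swap is *wrong* — a pure translation would carry the
  ghost tail outside the dimer basis — and the reflection route relies
  on the monomer's z → −z mirror symmetry, which every supported
  (planar) monomer has. In this mode E_xrb ≈ 0 and the orbitals are
  canonical in the full dimer basis.

## Orbital classification

Occupied MOs are labeled π if antisymmetric under z → −z and σ
otherwise; π orbitals are additionally labeled S/A under the σ_xz
mirror (y → −y) and ranked by energy within each parity class (the nS
and nA orbitals have n−1 nodal surfaces along the long axis). Parities
are measured as normalized reflection expectation values on the
real-monomer AO block (ghost centers generally break both mirrors), with
a purity threshold of 0.98; planar symmetric molecules give parities of
±1 up to numerical noise, so the threshold only guards against
mis-oriented input. Degenerate sets (energy window 1e-6 Hartree, e.g.
benzene's e-type orbitals) emerge from the SCF in an arbitrary internal
mixing and are rotated onto symmetry eigenvectors first — z-parity, then
y-parity within equal-z-parity subblocks. Individual pair terms inside a
degenerate set are representation dependent; only degenerate-set sums
are basis-stable, and grouped sums are always reported alongside.
Phases are fixed by making each orbital's largest-magnitude AO
coefficient positive (lowest AO index on ties).

## Electronic-structure backend

All integrals come from an in-package McMurchie–Davidson engine
(Cartesian Gaussians, Hermite expansion + Boys-function Coulomb
integrals, numba kernels) with Cauchy–Schwarz shell-pair screening at
1e-12 and primitive-level prefactor screening at 1e-16. Two-electron
integrals are held either as a dense 4-index tensor (≤ ~100 AOs; needed
for the occupied-block MO transforms) or in canonically packed 1D
storage with 8-fold permutational symmetry (used by the SCF for larger
systems, e.g. pentacene/6-31G at 226 AOs), behind a configurable memory
cap (default 4 GB) that refuses oversize requests with an estimate.
The restricted HF solver uses a Wolfsberg–Helmholz-type guess, DIIS,
symmetric orthogonalization with a 1e-10 linear-dependence cutoff, and
converges to 1e-10 Hartree in energy and 1e-8 RMS in the density —
tighter than usual so that 4-decimal orbital energies are stable.
Shipped basis sets: STO-3G, 3-21G, 6-31G (standard published parameter
tables). Density fitting is not implemented; the `density_fitting` flag
is rejected explicitly rather than ignored. Internal lengths are Bohr
(1 Å = 1.8897261254535 Bohr); energies are Hartree internally and
reported in kJ/mol (1 Hartree = 2625.499639 kJ/mol).

## Particle-in-a-box model

Box eigenfunctions of length L, one box shifted by Δ, a = Δ/L:

    S_B(n,m;a) = (2/π) [(−1)^{n+m} n sin(πma) − m sin(πna)] / (n² − m²)   (n ≠ m)
    S_B(n,n;a) = (1 − a) cos(πna) + sin(πna)/(nπ)

for 0 ≤ a ≤ 1 and exactly 0 for a ≥ 1 (disjoint boxes; no
extrapolation). The placement of the (−1)^{n+m} factor on the first
term only was fixed by re-deriving the integral in closed form and
checking against numerical quadrature at 1e-10 over n, m ≤ 12; with the
factor applied globally the formula would violate the exact
transposition relation S_B(m,n) = (−1)^{n+m} S_B(n,m). Quantum numbers
are strict integers in the public API; a private real-valued
antiderivative form exists only to check continuity of the two branches.
Defaults: L = 15 Å for long-axis scans (the extension of a
pentacene-sized π-system) and L = 6.3 Å for transverse scans (its
extension across the short axis including hydrogens, adopted as a
module constant); N = 6 and 5 model the mirror-symmetric and
antisymmetric π subsets of pentacene, and their combined squared sum
models the full π set.

## Scans and feature detection

Scans default to the 0.1 Å grid step used for the reference potential
curves. In `monomer` mode one monomer SCF serves every grid point (only
the inter-monomer AO integrals change); in `dimer_ghost` mode each
exchange-decomposition point recomputes the counterpoise SCF. Zeros are
located by sign change and refined with a local 3-point quadratic (roots
constrained to the bracketing interval, linear fallback); extrema by
discrete comparison plus quadratic vertex refinement; positions are
reported to 0.01 Å. Quadratic rather than spline refinement keeps the
procedure exactly reproducible. Shoulders are not detected automatically
— there is no objective criterion — but are visible in exported curves.
Failed scan points are recorded as NaN with a warning and listed in the
result's provenance; no on-disk scan cache is kept (results are plain
CSV with unit header comments).

External SAPT0 component tables (electrostatic/induction/dispersion/
exchange, kJ/mol) are ingestion-only: rows must satisfy
E_int = E_el + E_ind + E_dsp + E_exch to 0.01 kJ/mol (inclusive at the
printed rounding boundary) or the file is rejected listing the
offending rows. A reference table for the five acene dimers at
characteristic arrangements ships with the package.

## Independent references used by the tests

* A plain damped Roothaan SCF (no DIIS) cross-checks the production
  solver at 1e-8 Hartree.
* Every pair-term component is re-evaluated with explicit nested loops
  and an independently ordered MO transform (1e-10 agreement on He₂,
  H₂-dimer and ethylene-dimer fixtures at several separations).
* The total E_xr is compared with the exact nonorthogonal Heitler–London
  first-order exchange: the energy of the antisymmetrized product of
  the two monomer determinants evaluated via the Löwdin inverse-overlap
  density, minus monomer energies and classical electrostatics. This
  exact form replaces a hand-expanded S² truncation deliberately — the
  two differ at O(S⁴), far below the 5% comparison band at the tested
  separations, and the exact expression is a stronger reference.
* s-type repulsion integrals have an erf closed form, independent of the
  engine's Boys recursion.
* Box-model overlaps are checked against direct quadrature.

Oracles share the integral engine's AO matrices but none of its
MO-level algebra; they refuse systems beyond small fixed sizes.

## Built-in geometries and what passing tests show

Acene fixtures are idealized: fused regular hexagons with aromatic C–C
1.40 Å, C–H 1.09 Å, exact 120° angles. This reproduces every
combinatorial and symmetry property of optimized structures exactly
(orbital counts, pair counts, parities, selection rules) and places
overlap-curve features approximately: the idealized pentacene is ~1.5%
shorter along x than an optimized geometry with bond alternation, which
shifts long-axis feature positions inward by a few hundredths of an
Ångström. Optimized coordinates can be dropped in via `read_xyz` +
`canonical_orient` for quantitatively exact features.

Known accuracy limits (measured, not tuned): with 6-31G — the best
shipped basis — the pentacene HOMO energy is −0.2031 Hartree against
−0.2185 at the aug-style double-zeta reference level, and the cofacial
S(6S,6S) overlap is −0.064 against −0.08; both discrepancies are
dominated by the missing diffuse functions, which carry the outer tail
of the π density at 3.4 Å separation (STO-3G, for scale, gives −0.018).
Feature *positions* of the overlap curves are far less basis-sensitive:
the first zero / global maximum / first minimum of the pentacene
S(6S,6S) x-scan land at 1.30 / 2.49 / 4.94 Å versus the reference 1.40
/ 2.51 / 4.98 Å, the residual shift coming mostly from the idealized
geometry. The cofacial benzene exchange repulsion in the counterpoise
basis (65.9 kJ/mol) agrees with the externally computed SAPT0 exchange
energy (62.21 kJ/mol) to 6% — an approximate relation by construction,
since the two quantities differ in their treatment of higher-order
overlap terms. The σ–σ class carries ~2.4% of the cofacial benzene
repulsion, matching the qualitative picture that σ orbitals are
spectators.

A full pentacene-*dimer* pair decomposition (146 occupied orbitals,
≥ 424 AOs in a double-zeta basis) is beyond the dense-tensor path's
memory envelope and is not attempted in the test suite; the
decomposition's correctness at that scale rests on the size-independent
identities (component sum, group partitions, oracle equivalence) that
are exercised exhaustively on the small dimers.

## Problem sizes in the shipped runs

The test suite and acceptance script run, on one CPU: monomer SCFs up to
pentacene/6-31G (226 AOs, packed integrals, ~4–5 min), the benzene-dimer
decomposition in the counterpoise 6-31G basis (132 AOs, dense tensors,
~2–3 min), 141-point overlap scans (seconds after the SCF), and the
complete small-fixture oracle battery. These sizes were chosen as the
smallest systems that exhibit every phenomenon the package claims to
compute: multi-node π systems (pentacene), degenerate sets (benzene),
σ/π mixtures (all), and exact symmetry selection rules (Δy = 0 cuts).
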