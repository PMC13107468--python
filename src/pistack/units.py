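"""Physical constants and unit conversions.

All internal lengths are Bohr and energies Hartree; public I/O uses
Angstrom and, for reported energies, kJ/mol.
"""

BOHR_PER_ANGSTROM = 1.8897261254535
ANGSTROM_PER_BOHR = 1.0 / BOHR_PER_ANGSTROM

HARTREE_TO_KJMOL = 2625.499639
KJMOL_TO_HARTREE = 1.0 / HARTREE_TO_KJMOL
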