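6
idealized ethylene_dimer monomer, canonical orientation (synthetic)
C       0.6695000000       0.0000000000       0.0000000000
C      -0.6695000000       0.0000000000       0.0000000000
H       1.2336977555       0.9279422895       0.0000000000
H       1.2336977555      -0.9279422895       0.0000000000
H      -1.2336977555       0.9279422895       0.0000000000
H      -1.2336977555      -0.9279422895       0.0000000000
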