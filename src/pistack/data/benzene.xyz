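12
idealized benzene monomer, canonical orientation (synthetic)
C       0.7000000000       1.2124355653       0.0000000000
C      -0.7000000000       1.2124355653       0.0000000000
C       0.7000000000      -1.2124355653       0.0000000000
C      -0.7000000000      -1.2124355653       0.0000000000
C       1.4000000000       0.0000000000       0.0000000000
C      -1.4000000000       0.0000000000       0.0000000000
H       2.4900000000       0.0000000000       0.0000000000
H      -2.4900000000       0.0000000000       0.0000000000
H       1.2450000000       2.1564032554       0.0000000000
H      -1.2450000000       2.1564032554       0.0000000000
H       1.2450000000      -2.1564032554       0.0000000000
H      -1.2450000000      -2.1564032554       0.0000000000
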