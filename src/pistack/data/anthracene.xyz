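24
idealized anthracene monomer, canonical orientation (synthetic)
C       3.6373066959       0.7000000000       0.0000000000
C       3.6373066959      -0.7000000000       0.0000000000
C       1.2124355653       0.7000000000       0.0000000000
C       1.2124355653      -0.7000000000       0.0000000000
C      -1.2124355653       0.7000000000       0.0000000000
C      -1.2124355653      -0.7000000000       0.0000000000
C      -3.6373066959       0.7000000000       0.0000000000
C      -3.6373066959      -0.7000000000       0.0000000000
C       2.4248711306       1.4000000000       0.0000000000
C       2.4248711306      -1.4000000000       0.0000000000
C       0.0000000000       1.4000000000       0.0000000000
C       0.0000000000      -1.4000000000       0.0000000000
C      -2.4248711306       1.4000000000       0.0000000000
C      -2.4248711306      -1.4000000000       0.0000000000
H       2.4248711306       2.4900000000       0.0000000000
H       2.4248711306      -2.4900000000       0.0000000000
H       0.0000000000       2.4900000000       0.0000000000
H       0.0000000000      -2.4900000000       0.0000000000
H      -2.4248711306       2.4900000000       0.0000000000
H      -2.4248711306      -2.4900000000       0.0000000000
H       4.5812743860       1.2450000000       0.0000000000
H       4.5812743860      -1.2450000000       0.0000000000
H      -4.5812743860       1.2450000000       0.0000000000
H      -4.5812743860      -1.2450000000       0.0000000000
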