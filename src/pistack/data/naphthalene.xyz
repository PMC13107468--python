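18
idealized naphthalene monomer, canonical orientation (synthetic)
C       2.4248711306       0.7000000000       0.0000000000
C       2.4248711306      -0.7000000000       0.0000000000
C       0.0000000000       0.7000000000       0.0000000000
C       0.0000000000      -0.7000000000       0.0000000000
C      -2.4248711306       0.7000000000       0.0000000000
C      -2.4248711306      -0.7000000000       0.0000000000
C       1.2124355653       1.4000000000       0.0000000000
C       1.2124355653      -1.4000000000       0.0000000000
C      -1.2124355653       1.4000000000       0.0000000000
C      -1.2124355653      -1.4000000000       0.0000000000
H       1.2124355653       2.4900000000       0.0000000000
H       1.2124355653      -2.4900000000       0.0000000000
H      -1.2124355653       2.4900000000       0.0000000000
H      -1.2124355653      -2.4900000000       0.0000000000
H       3.3688388207       1.2450000000       0.0000000000
H       3.3688388207      -1.2450000000       0.0000000000
H      -3.3688388207       1.2450000000       0.0000000000
H      -3.3688388207      -1.2450000000       0.0000000000
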