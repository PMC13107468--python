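2
idealized h2_dimer monomer, canonical orientation (synthetic)
H       0.3700000000       0.0000000000       0.0000000000
H      -0.3700000000       0.0000000000       0.0000000000
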