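1
idealized he2 monomer, canonical orientation (synthetic)
He       0.0000000000       0.0000000000       0.0000000000
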