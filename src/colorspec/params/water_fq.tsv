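# FQ parameters for water: type  chi  eta  (a.u.)
# Placeholder literature-style values; edit to match a parametrized force field.
O   0.189194   0.623700
H   0.012767   0.637512
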