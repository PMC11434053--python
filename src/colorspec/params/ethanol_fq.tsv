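# FQ parameters for ethanol: type  chi  eta  (a.u.)
# Placeholder literature-style values; edit to match a parametrized force field.
O   0.189000   0.610000
H   0.012000   0.640000
C   0.077000   0.505000
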