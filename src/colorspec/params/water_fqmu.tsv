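# FQFmu parameters for water: type  chi  eta  alpha  (a.u.)
# Placeholder literature-style values; edit to match a parametrized force field.
O   0.256000   0.575700   3.466000
H   0.000000   0.624700   1.387000
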