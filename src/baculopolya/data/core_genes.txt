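# Default core-gene name table: protein-coding genes shared across the
# family (per-gene membership is configuration, not computation; edit to
# suit your annotation vocabulary).  Case-insensitive glob patterns.
polh
granulin
pif-0
pif-1
pif-2
pif-3
pif-4
pif-5
pif-6
pif-7
pif-8
p6.9
vp39
vp1054
vp91
gp41
odv-e18
odv-e25
odv-e27
odv-ec43
38k
49k
p33
p18
p40
p47
p48
p74
lef-1
lef-2
lef-4
lef-5
lef-8
lef-9
dnapol
helicase
alk-exo
desmoplakin
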