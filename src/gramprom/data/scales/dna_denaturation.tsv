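# property: dna_denaturation
# k: 2
# direction: peak
# editable defaults approximating published experimental scales
aa	66.5
ac	97.7
ag	84.9
at	72.6
ca	80.1
cc	99.3
cg	91.4
ct	84.9
ga	86.4
gc	111.1
gg	99.3
gt	97.7
ta	50.1
tc	86.4
tg	80.1
tt	66.5
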