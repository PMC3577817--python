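# property: b_dna_twist
# k: 2
# direction: cleft
# editable defaults approximating published experimental scales
aa	35.1
ac	31.5
ag	31.9
at	29.3
ca	37.3
cc	32.9
cg	36.1
ct	31.9
ga	36.3
gc	33.6
gg	32.9
gt	31.5
ta	37.8
tc	36.3
tg	37.3
tt	35.1
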