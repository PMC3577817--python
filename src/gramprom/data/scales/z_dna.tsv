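# property: z_dna
# k: 2
# direction: cleft
# editable defaults approximating published experimental scales
aa	3.9
ac	4.6
ag	3.4
at	5.9
ca	1.3
cc	2.4
cg	0.7
ct	3.4
ga	3.4
gc	4.0
gg	2.4
gt	4.6
ta	2.5
tc	3.4
tg	1.3
tt	3.9
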