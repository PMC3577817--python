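# property: a_philicity
# k: 2
# direction: cleft
# editable defaults approximating published experimental scales
aa	-0.06
ac	1.5
ag	0.68
at	1.07
ca	0.78
cc	0.7
cg	1.19
ct	0.68
ga	1.12
gc	1.62
gg	0.7
gt	1.5
ta	0.18
tc	1.12
tg	0.78
tt	-0.06
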