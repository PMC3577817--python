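# property: base_stacking
# k: 2
# direction: cleft
# editable defaults approximating published experimental scales
aa	-5.37
ac	-10.51
ag	-6.78
at	-6.57
ca	-6.57
cc	-8.26
cg	-9.69
ct	-6.78
ga	-9.81
gc	-14.59
gg	-8.26
gt	-10.51
ta	-3.82
tc	-9.81
tg	-6.57
tt	-5.37
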