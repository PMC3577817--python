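# property: propeller_twist
# k: 2
# direction: peak
# editable defaults approximating published experimental scales
aa	-18.66
ac	-13.1
ag	-14.0
at	-15.01
ca	-9.45
cc	-8.11
cg	-10.03
ct	-14.0
ga	-13.48
gc	-11.08
gg	-8.11
gt	-13.1
ta	-11.85
tc	-13.48
tg	-9.45
tt	-18.66
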