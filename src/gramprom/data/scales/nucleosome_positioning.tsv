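# property: nucleosome_positioning
# k: 3
# direction: peak
# editable defaults approximating published experimental scales
aaa	-0.36
aac	-0.09
aag	-0.12
aat	-0.3
aca	0.06
acc	0.08
acg	0.11
act	-0.03
aga	-0.05
agc	0.25
agg	0.09
agt	-0.03
ata	-0.13
atc	0.07
atg	0.18
att	-0.3
caa	-0.09
cac	0.17
cag	0.23
cat	0.18
cca	0.08
ccc	0.13
ccg	0.02
cct	0.09
cga	0.31
cgc	0.25
cgg	0.02
cgt	0.11
cta	-0.18
ctc	0.08
ctg	0.23
ctt	-0.12
gaa	-0.12
gac	0.01
gag	0.08
gat	0.07
gca	0.13
gcc	0.45
gcg	0.25
gct	0.25
gga	0.05
ggc	0.45
ggg	0.13
ggt	0.08
gta	-0.06
gtc	0.01
gtg	0.17
gtt	-0.09
taa	-0.2
tac	-0.06
tag	-0.18
tat	-0.13
tca	0.25
tcc	0.05
tcg	0.31
tct	-0.05
tga	0.25
tgc	0.13
tgg	0.08
tgt	0.06
tta	-0.2
ttc	-0.12
ttg	-0.09
ttt	-0.36
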