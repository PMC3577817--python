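# property: bendability
# k: 3
# direction: peak
# editable defaults approximating published experimental scales
aaa	-0.274
aac	-0.205
aag	-0.081
aat	-0.28
aca	-0.006
acc	-0.032
acg	-0.033
act	-0.183
aga	0.027
agc	-0.057
agg	-0.057
agt	-0.183
ata	0.182
atc	-0.11
atg	0.134
att	-0.28
caa	0.015
cac	0.04
cag	0.175
cat	0.134
cca	-0.246
ccc	-0.012
ccg	-0.136
cct	-0.057
cga	-0.003
cgc	-0.077
cgg	-0.136
cgt	-0.033
cta	0.09
ctc	0.031
ctg	0.175
ctt	-0.081
gaa	-0.037
gac	-0.013
gag	0.031
gat	-0.11
gca	0.076
gcc	0.107
gcg	-0.077
gct	-0.057
gga	0.013
ggc	0.107
ggg	-0.012
ggt	-0.032
gta	0.09
gtc	-0.013
gtg	0.04
gtt	-0.205
taa	0.068
tac	0.09
tag	0.09
tat	0.182
tca	0.194
tcc	0.013
tcg	-0.003
tct	0.027
tga	0.194
tgc	0.076
tgg	-0.246
tgt	-0.006
tta	0.068
ttc	-0.037
ttg	0.015
ttt	-0.274
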