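line	replicate	cc50
MDAMB436 Parent	1	0.0046
MDAMB436 Parent	2	0.0073
MDAMB436 Parent	3	0.0099
MDAMB436 Res Cell Line A1	1	0.5527
MDAMB436 Res Cell Line A1	2	2.5034
MDAMB436 Res Cell Line A1	3	1.4963
MDAMB436 Res Cell Line A2	1	0.8560
MDAMB436 Res Cell Line A2	2	1.1086
MDAMB436 Res Cell Line A2	3	3.5025
MDAMB436 Res Cell Line A3	1	0.8361
MDAMB436 Res Cell Line A3	2	2.4809
MDAMB436 Res Cell Line A3	3	2.366
HCC1428 Parent	1	0.308
HCC1428 Parent	2	0.480
HCC1428 Parent	3	0.520
HCC1428 Res Cell Line A	1	1.768
HCC1428 Res Cell Line A	2	2.245
HCC1428 Res Cell Line A	3	1.421
HCC1428 Res Cell Line B	1	1.932
HCC1428 Res Cell Line B	2	2.270
HCC1428 Res Cell Line B	3	2.168
HCC1428 Res Cell Line C	1	1.853
HCC1428 Res Cell Line C	2	2.439
HCC1428 Res Cell Line C	3	2.007
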