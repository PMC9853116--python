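name	bases	water_loss	carrier	flag	printed_mz
[BPA+H]+	BPA	0	proton	ok	-
[BPA+Na]+	BPA	0	Na	ok	-
[BPA+K]+	BPA	0	K	ok	-
[BPA-H2O+Na]+	BPA	1	Na	ok	-
[BPA-H2O+K]+	BPA	1	K	ok	-
[BPA+DHB-2H2O+H]+	BPA+DHB	2	proton	ok	-
[BPA+DHB-2H2O+Na]+	BPA+DHB	2	Na	ok	-
[BPA+DHB-2H2O+K]+	BPA+DHB	2	K	ok	-
[BPA+DHB-H2O+H]+	BPA+DHB	1	proton	ok	-
[2DHB-2H2O+H]+	2DHB	2	proton	ok	-
[2DHB-H2O+Na]+	2DHB	1	Na	ok	-
[2DHB-H2O+K]+	2DHB	1	K	ok	-
[DHB+H]+	DHB	0	proton	ok	-
[DHB+K]+	DHB	0	K	ok	-
[DHB-H+2K]+	DHB	0	2K-H	ok	-
[DHB-H2O]+	DHB	1	electron-loss	ok	-
[Na]+	-	0	Na	ok	-
[K]+	-	0	K	ok	-
[BPA+2DHB-2H2O+H]+	BPA+2DHB	2	proton	printed	464.115
[BPA+2DHB-H2O+H]+	BPA+2DHB	1	proton	printed	482.126
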