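# ESI adduct registry. delta = mass(add_formula) + protons*m_p + electrons*m_e,
# with m_p = 1.007276466 Da and m_e = 0.00054857991 Da.
# "electrons" is the net electron count gained by the ion (-1 for cations that
# lose an electron, +1 for anions that gain one beyond deprotonation bookkeeping).
# label	polarity	multiplicity	add_formula	protons	electrons
[M+H]+	+	1		1	0
[M+K]+	+	1	K	0	-1
[M+Na]+	+	1	Na	0	-1
[2M+H]+	+	2		1	0
[M-e]+	+	1		0	-1
[M+COOH]-	-	1	CHO2	0	1
[M-H]-	-	1		-1	0
[2M-H]-	-	2		-1	0
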