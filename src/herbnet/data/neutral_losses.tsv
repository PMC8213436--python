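# Default neutral-loss table for fragment assignment.
# rha = rhamnose residue (dehydrated), Glc = glucose residue (dehydrated).
# label	formula
rha	C6H10O4
Glc	C6H10O5
H2O	H2O
CO2	CO2
C4H7	C4H7
C4H8O4	C4H8O4
C3H6O3	C3H6O3
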