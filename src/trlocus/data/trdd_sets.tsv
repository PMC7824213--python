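Set	human	bovine	sheep
TRDD1	1 F	1 O	1 O (2)
TRDD2	1 F	1 F	1 F
TRDD3	1 F	1 O	1 O
TRDD4	-	1 F	1 F
TRDD5	-	1 O	1 O
TRDD6	-	1 F	1 F
TRDD7	-	1 F	1 O
TRDD8	-	1 F	1 F
TRDD9	-	1 F	1 F
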