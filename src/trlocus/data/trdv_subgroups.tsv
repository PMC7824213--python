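Subgroup	human	bovine	sheep
TRDV1	1 F	41 F (55), 4 O (5), 5 P	32 F (41), 11 O, 27 P (28), 5 FO (11), 6 FP (13), 3 OP (6)
TRDV2	1 F (3)	1 F	1 O (2)
TRDV3	1 F (2)	1 F	1 F (2)
TRDV4	-	1 O	1 P
TRDV5	-	2 F (4)	1 F (2)
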