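Subgroup	human	bovine	sheep
TRAV1	2 F (5)	1 F	1 O
TRAV2	1 F (2)	5 F, 2 P	1 O (2)
TRAV3	1 FP (2)	6 F, 1 FP (2)	1 F (2)
TRAV4	1 F	1 P	2 F (3)
TRAV5	1 F	1 F (3)	1 FP (2)
TRAV6	1 F (7)	1 P (2)	1 P (2)
TRAV7	1 F	-	-
TRAV8	5 F (17), 3 P (4)	1 F (3), 4 P (6)	5 F (6), 22 P (24), 1 FO (2), 2 FP (4)
TRAV9	2 F (5)	4 F (7), 2 P	7 F (8), 5 P (7)
TRAV10	1 F (2)	1 O, 2 P	1 F (2), 1 P
TRAV11	2 P	3 P	3 P (4)
TRAV12	3 F (7)	2 F, 1 FP (3)	5 F (6), 2 P
TRAV13	2 F (5)	2 F (4), 2 P (4)	11 F, 10 P
TRAV14	1 F (4), 1 P (2)	1 F, 1 O (2), 1 P, 1 FP (3)	7 F, 1 O, 6 P
TRAV15	1 P	-	-
TRAV16	1 F	1 F	1 F (2)
TRAV17	1 F	1 F (2), 2 P	1 P, 1 FP (2)
TRAV18	1 F	1 F, 2 O, 1 P (2), 1 FO (3)	3 F, 1 P
TRAV19	1 F	2 F, 1 P (2), 1 FOP (3)	1 P
TRAV20	1 F (4)	2 F (3), 1 O, 1 P	2 F, 2 P
TRAV21	1 F (2)	2 F (4), 1 O, 1 P	2 F (3), 3 P
TRAV22	1 F	6 F (7), 3 O, 5 P (7), 1 FO (3), 1 FP (3)	20 F (22), 22 P (24), 1 FP (2)
TRAV23	1 F (5)	1 F (2), 10 P (14), 2 OP (4)	5 F, 2 O, 32 P (37)
TRAV24	1 F (2)	1 F, 5 P (7), 1 FO (2)	1 F, 2 O, 5 P
TRAV25	1 F	4 F (6), 1 O, 9 P, 1 FP (2)	10 F (11), 2 O, 13 P, 1 FP (2)
TRAV26	2 F (5)	1 P (3)	2 F (3)
TRAV27	1 F (3)	1 OP (2)	1 FP (2)
TRAV28	1 P (2)	2 F (4), 1 P	2 F (4)
TRAV29	1 FP (4)	1 F (3), 1 O	2 F (3)
TRAV30	1 F (5)	-	-
TRAV31	1 P (2)	-	-
TRAV32	1 P	-	-
TRAV33	1 P	2 P (3), 1 FP (4)	1 F, 1 P (2)
TRAV34	1 F	2 P (4)	1 P
TRAV35	1 FP (3)	2 F	1 P (2)
TRAV36	1 F (5)	1 F, 1 P	1 F (2)
TRAV37	1 P	2 P	1 P
TRAV38	2 F (5)	6 F (9)	2 F (3)
TRAV39	1 F	1 F, 1 O	1 O (2)
TRAV40	1 F	1 P	-
TRAV41	1 F	1 F	1 F (2)
TRAV43	-	3 F (6)	13 F (15), 2 P (3)
TRAV44	-	8 F, 1 O, 8 P (11), 1 FP (2)	13 F (14), 1 O, 11 P (12)
TRAV45	-	10 F (14), 1 O, 2 P (3), 2 FP (4)	4 F (5), 1 P, 1 OP (2)
TRAV46	1 P	1 P	1 P (2)
TRAVA	1 P (2)	-	-
TRAVB	1 P (2)	-	-
TRAVC	1 P	-	-
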