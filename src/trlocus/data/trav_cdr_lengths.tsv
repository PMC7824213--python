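Subgroup	human	bovine	sheep
TRAV1	[6.6.3]	[6.6.3]	[6.6.3]
TRAV2	[6.4.3]	[6.4.3]	[6.4.3]
TRAV3	[6.8.4]	[6.8.3]	[6.8.3]
TRAV4	[7.5.4]	[7.5.4]	[7.5.4]
TRAV5	[6.7.3]	[6.7.3]	[6.7.3]
TRAV6	[6.7.3]	-	-
TRAV7	[6.7.3]	-	-
TRAV8	[6.8.3]	[6.8.3]	[6.8.3]
TRAV9	[6.7.3]	[6.7.3]	[6.7.3]
TRAV10	[6.7.3]	[5.7.3] [6.7.3]	[6.7.3]
TRAV11	[6.7.2]	[6.7.3]	[6.7.3]
TRAV12	[6.6.3]	[6.6.3]	[6.6.3]
TRAV13	[6.7.3]	[6.7.3]	[6.7.3]
TRAV14	[7.8.4]	[7.8.4]	[7.8.4]
TRAV16	[6.4.3]	[6.4.3]	[6.4.3]
TRAV17	[5.7.3]	[5.7.3] [6.7.3]	[6.7.3]
TRAV18	[6.6.3]	[6.6.3] [6.7.3]	[6.7.3]
TRAV19	[7.8.4]	[7.8.4]	[7.8.4]
TRAV20	[6.7.3]	[6.7.3] [4.7.3]	[6.7.3]
TRAV21	[6.7.3]	[6.7.3]	[6.7.3]
TRAV22	[5.5.3]	[5.5.3] [4.5.3]	[5.5.3]
TRAV23	[6.7.3]	[6.7.3]	[6.7.3]
TRAV24	[6.7.2]	[6.7.2]	[6.7.2]
TRAV25	[5.7.2]	[5.7.2]	[5.7.2]
TRAV26	[7.5.4]	[7.5.4]	[7.5.4]
TRAV27	[5.7.2]	[5.7.2]	-
TRAV28	-	[5.5.3]	[5.5.3]
TRAV29	[6.7.3]	[6.7.3]	[6.7.3]
TRAV30	[5.7.3]	-	-
TRAV33	-	-	[7.7.5]
TRAV34	[5.7.3]	-	-
TRAV35	[5.7.3]	[5.7.2]	[5.7.2]
TRAV36	[6.7.3]	[6.7.3]	[6.7.3]
TRAV38	[7.8.4]	[7.8.4] [8.8.4] [6.8.4]	[7.8.4]
TRAV39	[5.7.3]	[6.7.3]	[6.7.3]
TRAV40	[6.4.3]	-	-
TRAV41	[5.5.3]	[5.5.3]	[5.5.3]
TRAV43	-	[5.5.3]	[5.5.3]
TRAV44	-	[7.5.4]	[7.5.4]
TRAV45	-	[7.7.3]	[7.7.3]
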