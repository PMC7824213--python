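Set	human	bovine	sheep
TRAJ1	1 O	1 F	1 F
TRAJ2	1 O	1 F	1 F
TRAJ3	1 F	1 F	1 O (2)
TRAJ4	1 F	1 FP (2)	1 O
TRAJ5	1 F	1 F	1 F (2)
TRAJ6	1 F	1 F	1 O
TRAJ7	1 F	1 F	1 F
TRAJ8	1 FP (2)	2 F (3)	2 F
TRAJ9	1 F	1 F	1 F (2)
TRAJ10	1 F	1 F	1 F (2)
TRAJ11	1 F	1 F (2)	1 F
TRAJ12	1 F	1 F	1 F
TRAJ13	1 F (2)	1 P (2)	1 O
TRAJ14	1 F	1 P (2)	1 O
TRAJ15	1 F (2)	1 FP (2)	1 F
TRAJ16	1 F (2)	1 F	1 F
TRAJ17	1 F	1 F	1 F
TRAJ18	1 F	1 F	1 F
TRAJ19	1 O	1 P	1 P
TRAJ20	1 F	1 F	1 F
TRAJ21	1 F	1 F	1 F
TRAJ22	1 F	1 F	1 F
TRAJ23	1 F (2)	1 F	1 F
TRAJ24	1 F (3)	1 F	1 F
TRAJ25	1 O	1 F (2)	1 F
TRAJ26	1 F	1 O	1 F
TRAJ27	1 F	1 F	1 F
TRAJ28	1 F	1 F	1 F
TRAJ29	1 F	1 F	2 F, 1 O
TRAJ30	1 F	1 F	1 F, 1 P
TRAJ31	1 F	1 F (2)	1 F, 2 P
TRAJ32	1 F (2)	1 F	2 F (3), 1 P
TRAJ33	1 F	1 F	2 F, 1 P
TRAJ34	1 F	1 F	2 F, 1 P
TRAJ35	1 F	1 O	2 F (3), 1 P
TRAJ36	1 F	1 F	2 F, 1 P
TRAJ37	1 F (2)	1 F (2)	2 F (3), 1 P
TRAJ38	1 F	1 F	1 F, 1 P
TRAJ39	1 F	1 F (2)	1 F, 1 P
TRAJ40	1 F	1 F	1 F
TRAJ41	1 F	1 F (2)	1 F
TRAJ42	1 F	1 F	1 F
TRAJ43	1 F	1 F	1 F
TRAJ44	1 F	1 F	2 F
TRAJ45	1 F	1 F (2)	1 F
TRAJ46	1 F	1 F	1 F
TRAJ47	1 F (2)	1 F	1 F
TRAJ48	1 F	1 F	1 F
TRAJ49	1 F	1 F	1 F
TRAJ50	1 F	1 F	1 F
TRAJ51	1 P	-	-
TRAJ52	1 F	1 F	1 F
TRAJ53	1 F	1 F	1 F
TRAJ54	1 F	1 F	1 F
TRAJ55	1 P	-	-
TRAJ56	1 F	1 F	1 F
TRAJ57	1 F	1 F	1 F
TRAJ58	1 O	1 F	1 F
TRAJ59	1 O	1 F	1 F
TRAJ60	1 P	1 F	1 F
TRAJ61	1 O	1 P	1 P
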