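Attribute	human	bovine	sheep
chromosome	14 (FWD)	10 (REV)	7 (REV)
size_kb	1000	3331	2882
TRAV	56	183	277 (+16 non localized)
TRDV	3	39 (+16 non localized)	70 (+18 non localized)
TRAV/DV	5	0	0
TRDD	3	9	9
TRAJ	61	60	79 (+1 non localized)
TRDJ	4	4	4
TRAC	1	1	1
TRDC	1	1	1
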