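Subgroup	human	bovine	sheep
TRDV1	[7.3.4]	[5.3.4] [7.3.4] [8.1.4] [8.3.4] [9.3.3] [9.3.4] [9.3.15] [10.3.4] [18.3.4]	[7.3.3] [7.3.4] [7.3.5] [9.3.4] [13.3.4]
TRDV2	[8.3.4]	[9.3.4]	[9.3.4]
TRDV3	[7.6.2]	[7.6.4]	[7.6.4]
TRDV4	-	[8.3.4]	-
TRDV5	-	[7.3.5]	[7.3.5]
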