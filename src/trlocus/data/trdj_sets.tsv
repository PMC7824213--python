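Set	human	bovine	sheep
TRDJ1	1 F	1 F	1 F
TRDJ2	1 F	1 O	1 O
TRDJ3	1 F	1 F	1 F
TRDJ4	1 F	1 F	1 F
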