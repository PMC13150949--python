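>J2 synthetic mouse IGHJ head; FDYW
TTTGACTACTGG
>J3 synthetic mouse IGHJ head; FAYW
TTTGCTTACTGG
>J4 synthetic mouse IGHJ head; YYAMDYW
TACTACGCTATGGACTACTGG
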