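>V14-4 synthetic mouse IGHV 3' region; junction tail CTTG (Cys codon at -12)
GAGGACACAGCCACATACTTCTGTCTCAGAGCATGTACTACTGGG
>V14-1 synthetic mouse IGHV 3' region; junction tail CARD
GAGGACACTGCCGTGTATTATGCTGCAAGCTCTTGTGCAAGAGAT
>V1-9 synthetic mouse IGHV 3' region; junction tail CARG
GACGACTCAGCCGTCTACTACGCCGCTCGCTCATGTGCAAGAGGG
>V5-17 synthetic mouse IGHV 3' region; junction tail CMRY
GAAGATACTGGAATCTATTTCGCAGCTTCAGCTTGTATGAGATAT
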