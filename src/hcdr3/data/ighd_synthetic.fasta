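>D1-1 synthetic mouse IGHD, DFL16.1-style; frames: V-rich / L+R+stop / Y-rich
GTTATTACTACGGTAGTAGCTAC
>D1-2 synthetic mouse IGHD, D1 family variant
GTTATTACTACGGTAGTACCTAC
>D2-2 synthetic mouse IGHD, DSP2-style; frames: hydrophobic / LW+stop / Y-rich
TCTACTATGGTAACTAC
>D2-3 synthetic mouse IGHD, D2 family variant
TCTACTATGATTACGAC
>D4-1 synthetic mouse IGHD, DQ52-style short segment
CTAACTGGGAC
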