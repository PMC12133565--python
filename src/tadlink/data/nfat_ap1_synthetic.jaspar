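>NFAT_AP1_synthetic synthetic composite NFAT:AP1-like motif (GGAAA + spacer + TGACTCA); constructed in-package, not a database matrix
A [ 1 1 17 17 17 5 5 5 1 1 17 1 1 1 17 ]
C [ 1 1 1 1 1 5 5 5 1 1 1 17 1 17 1 ]
G [ 17 17 1 1 1 5 5 5 1 17 1 1 1 1 1 ]
T [ 1 1 1 1 1 5 5 5 17 1 1 1 17 1 1 ]
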