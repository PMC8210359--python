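>5.8S_rRNA#rRNA GenBank: J01871.1
CGACTCTTAGCGGTGGATCACTCGGCTCGTGCGTCGATGAAGAACGCAGCGCTAGCTGCG
AGAATTAATGTGAATTGCAGGACACATTGATCATCGACACTTCGAACGCACTTGCGGCCC
CGGGTTCCTCCCGGGGCTACGCCTGTCTGAGCGTCGCT
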