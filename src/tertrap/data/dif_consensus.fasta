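>dif Escherichia coli dif consensus (28 bp, XerC/XerD chromosome dimer resolution site); external literature sequence, replaceable
GGTGCGCATAATGTATATTATGTTAAAT
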