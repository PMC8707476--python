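>TerB Escherichia coli TerB displayed strand; lock G(6); conserved 12 bp core at positions 8-19
AATAAGTATGTTGTAACTAAAGT
>TerC Escherichia coli TerC displayed strand (74% identity to TerB over the 23 bp frame)
ATATAGGATGTTGTAACTAATAT
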