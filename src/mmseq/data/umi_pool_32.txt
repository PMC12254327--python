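TGGCCAAA
GGGTCTGA
CTGATGTA
ATAGACCC
CAAAAGGG
CGTCCTTT
CGTGTGGC
TAGGTGCC
CCGTATGC
GGCCGGGC
TCCTCAGG
TTAAGCGA
TCTTGATA
GCTATAGG
TCTGTATT
ACGAGGTT
TGCTGTAC
TTCCCGAT
ACCGGGTT
CAGTCTCT
TCCGGCAT
TGCAATAG
TTCACTGA
GCACTTAG
AATCTGTG
TTAGCCCC
CTTGGTGC
TCATTAGT
AACGGCTG
GTTAATCA
GTACTCGT
GTAGGCGT
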