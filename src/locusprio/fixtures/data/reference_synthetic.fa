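>chr20:18022300-18022440
GCGTCGAAATGACAGAAAAGTTGATTACACCATTTGATGCTATCCGACTACCGTTATACATACGCTCAGT
CCTACTAACATGCTCTGCGTGGGCGTCTGCATACAGTTGGCATCTGACGCATTCACTCGCGAGTTAATCA
T
>chr20:30616700-30616990
ATCGACCGCAGTACTGTCTGGTATTGTTCGCTGCCACGGCAGCTATACGGGGTCGGGTATCCCGAGTCCC
GAATTTTCTCTTCTCGCTCTGCAAAGGGGCAATGACCTAAGGGTAGTCGCGTACGTACGAGTCCTGAACA
TCGAACGGGAGTGGCCTCGTGCTACGTCTCGCTTATGGCCGCCAAAATTAGGCTGACTTGGCCCTATACA
ACGCCAAACGCTGGCGAACAGTCGCTGAACACAATGAGGTGCCCCTCCGAATTTTAAGCTATCCTTGAGG
AGGCGTACTGA
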