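gene	specificity	sense	antisense	product_bp
CAMK2N1	methylated	AATTAGGAGGGGACGTTAAAATC	ACATATATCCCTAACAAACAACGAA	185
CAMK2N1	unmethylated	GAATTAGGAGGGGATGTTAAAATT	ACATATATCCCTAACAAACAACAAA	186
ALDH1A3	methylated	GTTCGTTTATTGACGAAATTTTTTC	AAAAACCGTACGCTTCTACGAC	134
ALDH1A3	unmethylated	TTGTTTATTGATGAAATTTTTTTGG	ACAAAAAACCATACACTTCTACAAC	135
PPP1R3C	methylated	ATTTGTTTTTAAGTACGTGATTCGA	GATACCCAAATAACTCTCTACACGTC	153
PPP1R3C	unmethylated	ATTTGTTTTTAAGTATGTGATTTGA	AATACCCAAATAACTCTCTACACATC	153
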