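>fungal_58S_consensus synthetic consensus of the conserved fungal 5.8S rRNA used as the default splitting anchor
AACTTTCAGCAACGGATCTCTTGGTTCTCGCATCGATGAAGAACGCAGCGAAATGCGATA
AGTAATGTGAATTGCAGAATTCAGTGAATCATCGAATCTTTGAACGCACCTTGCGCTCCT
TGGTATTCCGAGGAGCATGCCTGTTTGAGTGTCATGAAAT
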