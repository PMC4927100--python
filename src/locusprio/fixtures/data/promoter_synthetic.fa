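>promoter_ref synthetic
GCGCGCGCGCGCGTTGTTAATGCAGGCAGGCAGGCAGGCAG
>promoter_alt synthetic
GCGCGCGCGCGCGTTGTTAACGCAGGCAGGCAGGCAGGCAG
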