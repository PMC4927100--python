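chr20	17316433	26319280
chr20	29420137	31826081
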