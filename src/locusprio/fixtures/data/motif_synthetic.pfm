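>SYNFOX1 synthetic-forkhead-like
A [ 10 10 10 10 10 10 70  1 ]
C [ 10 10 10 10 10 10 10 97 ]
G [ 10 10 70 10 10 10 10  1 ]
T [ 70 70 10 70 70 70 10  1 ]
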