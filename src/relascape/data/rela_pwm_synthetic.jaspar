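>SYN0001.1 RELA_synthetic
A [  5  5  2 60 55 10  5  5  3  5 ]
C [  5  5  2  5 15  5 25 30 88 85 ]
G [ 85 85 94 30 15  5  5  5  3  5 ]
T [  5  5  2  5 15 80 65 60  6  5 ]
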