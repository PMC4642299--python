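# Default HSCR candidate (seed) gene list used for network linking.
# User-replaceable via --seeds / the seeds option.
RET
GDNF
NRTN
PSPN
EDNRB
EDN3
ECE1
NTF3
NTRK3
SOX10
PHOX2B
L1CAM
ZFHX1B
KIAA1279
TCF4
PROK1
PROKR1
PROKR2
GFRA1
NRG1
NRG3
SEMA3A
SEMA3C
SEMA3D
DNMT3B
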