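linker,span_angstrom,mean,sem,n
M1M,7,0.65,0.02,12
M3M,9,0.4556,0.03,9
bMTSp,12,0.3097,0.05,6
M6M,13,0.3,0.04,7
M8M,15,0.3389,0.04,9
M10M,18,0.5431,0.03,16
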