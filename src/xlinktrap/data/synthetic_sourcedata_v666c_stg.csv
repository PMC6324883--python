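linker,span_angstrom,mean,sem,n
M1M,7,0.3653,0.04,7
M3M,9,0.3163,0.03,9
bMTSp,12,0.3041,0.05,6
M6M,13,0.3163,0.04,8
M8M,15,0.3653,0.06,6
M10M,18,0.5,0.05,9
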