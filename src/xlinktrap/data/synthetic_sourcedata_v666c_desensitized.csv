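linker,span_angstrom,mean,sem,n
M1M,7,0.1653,0.03,9
M3M,9,0.1163,0.02,8
bMTSp,12,0.1041,0.04,5
M6M,13,0.1163,0.03,7
M8M,15,0.1653,0.05,6
M10M,18,0.3,0.06,8
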