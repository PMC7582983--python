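,WAKE,REM,N1,N2,N3,Epoch Count
WAKE,153,41,0,12,15,221
REM,40,292,10,0,0,342
N1,13,13,102,14,11,153
N2,8,10,14,857,10,899
N3,0,0,7,22,213,242
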