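stage,A,B,C,D,E
WAKE,-2.84,-1.32,0.33,-0.20,-0.09
REM,-1.80,-0.44,0.27,0.61,0.54
N1,-2.68,-0.15,0.24,0.15,0.25
N2,0.21,0.86,-0.32,-0.19,-0.11
N3,-2.71,0.23,-0.53,-0.64,-0.39
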