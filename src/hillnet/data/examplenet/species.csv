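ID,name,Yinit,Ymax,tau
A,Species A,0.0,1.0,1.0
B,Species B,0.0,1.0,1.0
C,Species C,0.0,1.0,1.0
D,Species D,0.0,1.0,1.0
E,Species E,0.0,1.0,1.0
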