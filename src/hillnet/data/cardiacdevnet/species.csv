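ID,name,Yinit,Ymax,tau
GATA6,GATA6,0.0,1.0,1.0
NKX25,NKX2-5,0.0,1.0,1.0
TBX1,TBX1,0.0,1.0,1.0
ISL1,ISL1,1.0,1.0,1.0
PITX2,PITX2,0.0,1.0,1.0
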