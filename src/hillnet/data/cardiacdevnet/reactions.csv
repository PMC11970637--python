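module,ID,Rule,Weight,n,EC50
,r1,=> GATA6,0.0,1.4,0.5
,r2,GATA6 => NKX25,1.0,1.4,0.5
,r3,GATA6 => TBX1,1.0,1.4,0.5
,r4,NKX25 => TBX1,1.0,1.4,0.5
,r5,TBX1 => PITX2,1.0,1.4,0.5
,r6,NKX25 => PITX2,1.0,1.4,0.5
,r7,!NKX25 => ISL1,1.0,1.4,0.5
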