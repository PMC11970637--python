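module,ID,Rule,Weight,n,EC50
,r1,=> A,0.0,1.4,0.5
,r2,=> B,0.0,1.4,0.5
,r3,A => C,1.0,1.4,0.5
,r4,B => D,1.0,1.4,0.5
,r5,C & !D => E,1.0,1.4,0.5
,r6,E => C,1.0,1.4,0.5
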