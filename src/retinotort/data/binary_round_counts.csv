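round,class,label,E1,E2,E3,E4,E5
R1,0,asymptomatic,53,39,44,45,49
R1,1,symptomatic,7,21,16,15,11
R2,0,asymptomatic,37,39,34,27,50
R2,1,symptomatic,23,21,26,33,10
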