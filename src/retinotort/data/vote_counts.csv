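class,label,V_R1,V_R2,V_R1R2,Rc
0,asymptomatic,52,37,45,44
1,symptomatic,8,23,15,16
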