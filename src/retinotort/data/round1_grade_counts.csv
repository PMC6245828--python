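grade,label,E1,E2,E3,E4,E5
0,none,34,10,21,20,31
1,mild,19,29,23,25,18
2,moderate,7,20,16,12,11
3,severe,0,1,0,3,0
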