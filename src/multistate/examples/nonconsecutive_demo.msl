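species:
Demo(s1{free,bound,hidden}, s2{2,4,6,8,0}) = 1

reactions:
Demo(s1{free}, s2{2}) -> Demo(succ(s1), succ(s2)) : MA(kd)

globals:
kd = 1
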