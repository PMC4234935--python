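species:
Cdh1(p{0:maxP}) = 1
ClbM = 1

reactions:
Cdh1(p{0:maxP-1}) + ClbM -> Cdh1(succ(p)) + ClbM : MA(kphos)
Cdh1(p{1:maxP}) -> Cdh1(pred(p)) : MA(kdeph)

globals:
maxP = 10
kphos = 1
kdeph = 1
Cdh1T := SUM(Cdh1;p{1:maxP})
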