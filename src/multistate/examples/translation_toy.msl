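species:
R(c{1:len}) = 1
P1(c{1:len}) = 0
P2 = 0
M(c) := SUM(R;c{M.c+1:M.c+w})

reactions:
R(c{1:d}) -> P1(c=succ(R.c)) + P2 ; M(c=R.c) : MA(ktrans)

globals:
len = 20
d = 3
w = 14
ktrans = 1
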