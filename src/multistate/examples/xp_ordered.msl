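species:
XP(i{0:N}) = 1
Kin = 1

reactions:
XP(i{0:N-1}) + Kin -> XP(succ(i)) + Kin : MA(k)

globals:
N = 5
k = 1

functions:
dis(GLQ N, SITE i, GLQ k, SUB X, SUB K) = (N-i)*k*X*K
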