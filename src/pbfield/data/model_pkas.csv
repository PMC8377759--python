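label,type,pka
ASP,acid,3.65
GLU,acid,4.45
HIS,base,6.45
CYS,acid,8.30
TYR,acid,9.60
LYS,base,10.40
ARG,base,12.00
NTR,base,8.00
CTR,acid,3.20
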