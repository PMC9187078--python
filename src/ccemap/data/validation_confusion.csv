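true_class,MES0,MES1,MES2,MES3,INADEQUATE,ILEAL
MES0,109067,315,3,8,256,72
MES1,637,13990,12,23,87,4
MES2,158,32,3203,41,73,0
MES3,624,26,18,19746,322,0
INADEQUATE,1345,129,14,43,105046,0
ILEAL,9,0,0,0,0,74
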