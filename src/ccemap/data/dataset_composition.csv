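class,training,validation
MES0,112544,109721
MES1,60367,14753
MES2,8710,3507
MES3,21153,20736
INADEQUATE,280368,106577
ILEAL,502,83
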