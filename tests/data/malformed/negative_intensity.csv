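feature_id,mz,rt,mode,s1,s2
F001,100.0,50.0,positive,-5,2
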