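feature_id,mz,rt,mode
F001,100.0,50.0,positive
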