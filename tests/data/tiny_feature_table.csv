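feature_id,mz,rt,mode,plant_50_1,plant_50_2,plant_50_3,plant_50_4,plant_50_5,control_50_1,control_50_2,control_50_3
F001,211.0481,120.5,positive,1000,1100,950,1020,1080,240,260,250
F002,234.0373,121.0,positive,400,440,390,410,430,95,105,100
F003,180.0634,300.0,positive,500,520,NA,505,515,510,495,505
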