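sample_id,soil_type,solution,replicate
plant_50_1,plant,50,1
plant_50_2,plant,50,2
plant_50_3,plant,50,3
plant_50_4,plant,50,4
plant_50_5,plant,50,5
control_50_1,control,50,1
control_50_2,control,50,2
control_50_3,control,50,3
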