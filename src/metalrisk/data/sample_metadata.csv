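sample_id,protein_type,serving_mass_g,weighed_mass_g
P1,mixed plant,60,0.4508
P2,pea,30,0.4885
P3,soy,28.5,0.4961
P4,whey,30.4,0.4788
P5,whey,25,0.4762
P6,whey,25,0.4515
P7,whey,25,0.4122
P8,whey,25,0.4391
P9,whey,25,0.4619
P10,whey,25,0.4287
P11,whey,30.4,0.4708
P12,pea,10,0.4391
P13,whey,30.4,0.4524
P14,whey,30,0.4701
P15,whey,30,0.4933
P16,whey,30,0.4946
P17,whey,25,0.4163
P18,whey,42,0.4302
P19,casein,33,0.4493
P20,whey,25,0.4641
P21,whey,25,0.4423
P22,soy,10,0.4276
P23,whey,25,0.5074
P24,whey,30,0.4548
P25,whey,35,0.4389
P26,whey,35,0.441
P27,whey,25,0.4935
P28,whey,29.4,0.4993
P29,mixed plant,35,0.4882
P30,whey,28,0.4882
P31,whey,25,0.5096
P32,whey,28,0.5114
P33,blend,28,0.4136
P34,whey,30,0.4803
P35,whey,30,0.4139
P36,blend,50,0.4746
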