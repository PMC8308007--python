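element,rfd_ug_per_kg_day,csf_per_ug_per_kg_day,rda_ug_day,ul_ug_day,in_hi_list,in_cr_list
Li,2.0,,1000,,True,False
Be,2.0,4300,,,True,True
Mo,5.0,,45,2000,True,False
Cd,1.0,380,,,True,True
Sn,600.0,,,,True,False
Ba,200.0,,,,True,False
Pt,,,,,False,False
Au,,,,,False,False
Hg,0.3,,,,True,False
Tl,0.01,,,,True,False
Pb,3.5,8.5,,,True,True
Bi,,,,,False,False
Mg,,,6000,350000,False,False
Al,1000.0,,,,True,False
Ti,,,,,False,False
V,5.04,,,18000,True,False
Cr,3.0,500,,,False,False
Mn,140.0,,2300,11000,True,False
Fe,700.0,,8000,45000,True,False
Co,0.3,,,,True,False
Cu,40.0,,900,10000,True,False
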