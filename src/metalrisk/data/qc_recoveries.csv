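element,level_ug_per_L,pct_recovery,rsd_percent,n,control_kind,annotation
Li,0.2,98.1,18.8,2,matrix_spike,carryover
Li,1,95.2,13,3,matrix_spike,
Li,5,92.7,7.2,3,matrix_spike,
Li,15,96.6,4.6,3,matrix_spike,
Li,40,99.5,4,3,matrix_spike,
Be,0.2,116.6,1.4,3,matrix_spike,
Be,1,102.8,2.1,3,matrix_spike,
Be,5,101.8,2.1,3,matrix_spike,
Be,15,103.1,3.9,3,matrix_spike,
Be,40,104.6,3.2,3,matrix_spike,
Mo,0.2,123.2,0.9,3,matrix_spike,
Mo,1,101.2,0.5,3,matrix_spike,
Mo,5,98.2,0.6,3,matrix_spike,
Mo,15,100.4,1.1,3,matrix_spike,
Mo,40,99.8,0.4,3,matrix_spike,
Cd,0.2,111,1.3,3,matrix_spike,
Cd,1,97.4,1.1,3,matrix_spike,
Cd,5,96.4,0.9,3,matrix_spike,
Cd,15,97.3,1.4,3,matrix_spike,
Cd,40,101.1,1.2,3,matrix_spike,
Sn,0.2,118.2,0.5,3,matrix_spike,
Sn,1,105.3,0.5,3,matrix_spike,
Sn,5,101,0.5,3,matrix_spike,
Sn,15,104.3,1.2,3,matrix_spike,
Sn,40,100.3,0.8,3,matrix_spike,
Ba,0.2,96.6,0.2,3,matrix_spike,
Ba,1,95.4,1.5,3,matrix_spike,
Ba,5,111.9,0.5,3,matrix_spike,
Ba,15,104.8,1.1,3,matrix_spike,
Ba,40,101.2,0.8,3,matrix_spike,
Pt,0.2,100.3,9.9,3,matrix_spike,
Pt,1,97.5,1.3,3,matrix_spike,
Pt,5,100.6,0.8,3,matrix_spike,
Pt,15,101.4,0.3,3,matrix_spike,
Pt,40,100.2,0.3,3,matrix_spike,
Au,0.2,103.9,0.8,3,matrix_spike,
Au,1,93.3,0.1,3,matrix_spike,
Au,5,98.6,0.3,3,matrix_spike,
Au,15,99.4,0.6,3,matrix_spike,
Au,40,99.9,0.7,3,matrix_spike,
Hg,0.2,87.8,1.9,2,matrix_spike,carryover
Hg,1,96.9,4.3,3,matrix_spike,
Hg,5,97.2,0.3,3,matrix_spike,
Hg,15,99.1,0.3,3,matrix_spike,
Hg,40,102.6,0.6,3,matrix_spike,
Tl,0.2,93.5,9.9,3,matrix_spike,
Tl,1,95.6,8.9,3,matrix_spike,
Tl,5,94.7,9,3,matrix_spike,
Tl,15,95.2,8.2,3,matrix_spike,
Tl,40,94.5,8.2,3,matrix_spike,
Pb,0.2,97.8,1.5,3,matrix_spike,
Pb,1,99.9,2.2,3,matrix_spike,
Pb,5,108.3,1.2,3,matrix_spike,
Pb,15,103.1,1.5,3,matrix_spike,
Pb,40,100.8,1.6,3,matrix_spike,
Bi,0.2,101.2,1.6,3,matrix_spike,
Bi,1,100.7,0.9,3,matrix_spike,
Bi,5,100.2,0.7,3,matrix_spike,
Bi,15,101.7,1.4,3,matrix_spike,
Bi,40,99.7,1.9,3,matrix_spike,
Mg,15,89.5,5.3,2,readback,readback_12.5
Mg,40,116.3,3.5,3,matrix_spike,
Al,5,115,12.6,2,readback,readback_4
Al,15,98.5,0.0,2,readback,readback_12.5
Al,40,112.6,3.6,3,matrix_spike,
Ti,0.2,105.2,12.8,2,matrix_spike,carryover
Ti,1,101.3,3.4,3,matrix_spike,
Ti,5,101.2,2.2,3,matrix_spike,
Ti,15,101.8,2.3,3,matrix_spike,
Ti,40,100.5,0.6,3,matrix_spike,
V,0.2,95.9,10.2,3,matrix_spike,
V,1,96.4,5.4,3,matrix_spike,
V,5,97.1,0.4,3,matrix_spike,
V,15,98.3,2.5,3,matrix_spike,
V,40,98.3,1,3,matrix_spike,
Cr,0.2,93.3,2.4,2,readback,readback_0.25
Cr,1,117.1,3.3,3,matrix_spike,
Cr,5,101.4,1.2,3,matrix_spike,
Cr,15,101.2,2.1,3,matrix_spike,
Cr,40,99.2,0.3,3,matrix_spike,
Mn,0.2,98.7,1.6,2,readback,readback_0.25
Mn,1,90.3,0.1,2,readback,readback_1.5
Mn,5,117.2,0.9,3,matrix_spike,
Mn,15,100.8,3.4,3,matrix_spike,
Mn,40,99.3,1.7,3,matrix_spike,
Fe,15,109.8,2.8,3,matrix_spike,
Fe,40,105.4,2.0,3,matrix_spike,
Co,0.2,96.3,7.9,3,matrix_spike,
Co,1,96.5,6.0,3,matrix_spike,
Co,5,97.6,1.2,3,matrix_spike,
Co,15,98.3,4.0,3,matrix_spike,
Co,40,99.3,2.8,3,matrix_spike,
Cu,1,94.7,4.7,2,readback,readback_1.5
Cu,5,94.3,6.6,2,readback,readback_4
Cu,15,94.3,4.4,2,readback,readback_12.5
Cu,40,91.8,1.6,2,readback,readback_35
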