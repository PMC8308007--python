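sample_id,Li,Be,Mo,Cd,Sn,Ba,Pt,Au,Hg,Tl,Pb,Bi,Al,Ti,V,Cr,Mn,Fe,Co,Cu
P1,<17.4,5.6,1314.7,58.1,17.7,1868.8,19.9,24.6,18.4,3.1,49.5,2.7,NR*,661.2,60.2,424.2,NR*,NR*,115.2,NR*
P2,30.3,<0.9,1492.6,40.6,26.7,319.3,102.7,10.8,4.3,0.3,22.2,0.8,NR*,709.0,40.8,289.2,NR*,NR*,188.5,NR*
P3,90.3,<0.9,868.7,20.7,<17.4,1894.7,21.0,8.7,4.8,0.2,15.1,0.5,NR*,424.8,16.5,111.3,NR*,NR*,37.8,NR*
P4,<17.4,<0.9,707.2,6.6,<17.4,551.7,75.8,7.9,1.4,0.7,5.3,4.1,2068.5,308.4,2.3,81.4,149.1,5966.7,5.0,952.1
P5,<17.4,<0.9,2165.8,12.5,<17.4,598.0,68.3,7.8,1.5,0.0,2.7,5.9,1298.7,34.3,0.9,74.9,130.5,NR*,5.2,1068.0
P6,<17.4,<0.9,1184.1,9.4,<17.4,345.9,31.4,6.9,1.6,0.1,3.3,6.9,1525.1,29.7,2.5,51.4,153.3,NR*,3.3,905.0
P7,<17.4,<0.9,1530.6,13.4,<17.4,1326.6,28.0,7.9,1.9,1.1,7.8,8.0,3467.5,235.8,9.4,195.5,1909.3,NR*,39.4,3837.0
P8,<17.4,<0.9,942.8,8.9,<17.4,711.6,43.4,26.2,1.3,0.2,5.0,2.3,1263.7,30.6,0.6,58.9,113.7,7456.8,4.0,1077.9
P9,81.0,<0.9,1813.1,19.3,<17.4,2003.6,52.2,13.4,4.5,1.8,5.5,0.6,NR*,688.5,27.4,469.8,3794.2,NR*,93.8,4381.0
P10,<17.4,<0.9,1821.3,12.3,<17.4,1409.9,51.6,9.2,<0.2,1.0,8.6,3.5,2095.5,65.8,3.8,96.8,190.6,NR*,6.4,1266.7
P11,<17.4,<0.9,219.6,8.6,<17.4,667.7,43.9,9.9,2.7,2.0,5.9,4.2,6175.7,422.3,29.3,142.1,3132.3,NR*,39.2,2700.4
P12,54.4,5.5,2348.7,15.4,329.7,263.7,43.5,7.4,<0.2,0.3,22.5,1.0,NR*,677.2,43.5,210.7,NR*,NR*,89.5,NR*
P13,<17.4,<0.9,832.8,14.8,<17.4,1874.9,27.9,6.5,3.7,2.1,11.2,1.5,NR*,2042.1,45.7,234.5,3806.6,NR*,88.8,3268.4
P14,<17.4,<0.9,669.8,7.1,<17.4,1088.9,19.2,7.6,<0.2,0.4,5.2,38.9,1544.2,69.1,2.7,77.5,460.1,6712.4,3.7,1210.8
P15,<17.4,<0.9,663.7,10.1,<17.4,1695.9,23.8,6.3,4.9,1.2,9.2,28.0,NR*,1131.8,24.9,247.3,2294.4,NR*,60.5,2615.9
P16,34.3,<0.9,1538.3,14.9,<17.4,2388.8,24.0,6.0,0.8,1.7,19.3,3.0,NR*,1586.0,51.6,478.8,2738.6,NR*,59.5,3280.2
P17,<17.4,<0.9,1797.1,21.0,<17.4,2066.5,42.5,8.4,3.7,1.8,10.3,8.9,NR*,1298.9,30.7,477.9,3506.8,NR*,75.8,6523.8
P18,<17.4,<0.9,280.8,14.2,<17.4,1486.6,26.2,10.6,1.0,1.7,19.5,18.4,NR*,1228.1,31.0,627.2,3697.3,NR*,85.6,3944.2
P19,<17.4,<0.9,546.8,17.0,<17.4,4744.3,18.3,6.2,7.6,2.0,22.3,18.8,NR*,1585.5,51.8,302.9,4782.9,NR*,121.6,3727.2
P20,<17.4,<0.9,859.1,13.5,<17.4,2377.3,18.1,5.3,2.9,2.3,58.8,6.9,NR*,1753.1,35.9,604.8,3812.5,NR*,90.3,4717.6
P21,<17.4,<0.9,1532.0,23.2,<17.4,2241.5,13.2,7.3,8.1,1.6,17.6,5.9,NR*,1294.7,26.2,597.3,5001.5,NR*,95.7,4894.9
P22,142.0,<0.9,1223.1,23.4,<17.4,1676.5,12.9,7.0,3.0,0.2,26.1,<0.1,NR*,534.5,16.7,77.7,NR*,NR*,48.7,NR*
P23,33.1,<0.9,1320.3,12.3,<17.4,864.0,16.1,5.8,1.8,0.6,3.8,5.0,3840.2,416.3,10.3,229.4,2004.6,NR*,46.7,2765.2
P24,<17.4,<0.9,295.9,14.3,<17.4,1655.5,17.7,10.3,1.9,1.5,17.5,26.9,NR*,1527.8,41.8,703.0,4153.4,NR*,97.1,4553.6
P25,<17.4,<0.9,956.5,13.2,<17.4,1156.0,18.3,12.3,3.8,0.4,4.4,5.3,2848.8,80.1,7.0,50.1,2487.4,NR*,7.1,3315.4
P26,<17.4,<0.9,935.2,14.9,<17.4,1388.7,15.7,5.4,<0.2,0.1,10.8,8.0,NR*,150.7,6.3,62.2,4402.0,NR*,7.1,4516.8
P27,<17.4,<0.9,1176.1,18.9,<17.4,1748.8,18.4,6.3,1.1,1.7,14.2,2.3,NR*,985.4,28.2,442.5,2874.4,NR*,64.8,3110.4
P28,<17.4,<0.9,1688.9,10.7,<17.4,1254.3,30.7,8.9,1.4,1.0,88.4,3.7,1770.0,107.3,5.2,71.1,303.6,NR*,8.7,1171.0
P29,<17.4,<0.9,727.3,45.1,30.5,2891.0,16.2,8.8,1.4,0.3,21.9,<0.1,NR*,934.6,28.4,220.7,NR*,NR*,19.0,6187.1
P30,<17.4,<0.9,1000.5,15.5,<17.4,1369.4,13.3,5.6,0.9,1.2,7.7,1.5,NR*,683.8,20.9,283.5,2237.0,NR*,52.0,2464.9
P31,<17.4,<0.9,100.2,<0.61,<17.4,460.9,12.4,7.7,<0.2,0.3,0.8,0.7,1197.0,45.4,<0.6,106.4,226.3,4190.5,2.5,573.5
P32,<17.4,<0.9,1259.1,8.4,<17.4,971.8,23.1,5.7,<0.2,0.6,11.2,1.4,1770.7,149.6,3.8,99.6,100.8,6145.4,2.9,746.1
P33,<17.4,<0.9,1260.1,12.9,<17.4,1686.7,17.6,7.7,<0.2,0.5,23.8,2.9,6356.1,528.9,12.1,271.1,2339.9,NR*,17.6,3691.6
P34,<17.4,<0.9,338.0,15.5,<17.4,2253.9,17.3,13.8,6.9,3.4,66.0,17.8,NR*,2313.7,74.1,481.0,5960.4,NR*,162.1,5654.3
P35,<17.4,<0.9,266.1,5.4,<17.4,559.1,15.8,7.5,<0.2,0.0,3.6,21.3,1275.1,94.3,2.5,68.3,220.8,2550.5,3.7,664.2
P36,63.9,<0.9,957.6,23.1,<17.4,1300.5,17.0,7.7,<0.2,0.4,19.8,2.2,NR*,965.3,78.6,222.6,NR*,NR*,28.0,NR*
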