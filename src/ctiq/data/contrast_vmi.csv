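concentration_mg_ml,keV,version,level,mean_hu,sd_hu
2.0,40,V1,mild,138,4.0
2.0,40,V1,standard,142,2.5
2.0,40,V1,strong,143,3.0
2.0,40,V2,mild,148,5.1
2.0,40,V2,standard,149,3.6
2.0,40,V2,strong,155,5.0
2.0,50,V1,mild,97,1.9
2.0,50,V1,standard,101,2.0
2.0,50,V1,strong,96,2.8
2.0,50,V2,mild,98,2.2
2.0,50,V2,standard,102,4.0
2.0,50,V2,strong,98,3.5
2.0,60,V1,mild,69,1.7
2.0,60,V1,standard,67,1.0
2.0,60,V1,strong,67,1.5
2.0,60,V2,mild,70,1.9
2.0,60,V2,standard,68,2.8
2.0,60,V2,strong,70,3.1
2.0,70,V1,mild,46,1.2
2.0,70,V1,standard,45,0.8
2.0,70,V1,strong,44,1.0
2.0,70,V2,mild,49,1.1
2.0,70,V2,standard,48,1.0
2.0,70,V2,strong,48,1.4
1.0,40,V1,mild,83,5.0
1.0,40,V1,standard,89,8.0
1.0,40,V1,strong,86,4.5
1.0,40,V2,mild,80,4.5
1.0,40,V2,standard,81,6.4
1.0,40,V2,strong,80,5.1
1.0,50,V1,mild,54,2.8
1.0,50,V1,standard,53,7.0
1.0,50,V1,strong,51,4.1
1.0,50,V2,mild,52,3.2
1.0,50,V2,standard,49,3.3
1.0,50,V2,strong,48,3.8
1.0,60,V1,mild,35,1.6
1.0,60,V1,standard,38,5.0
1.0,60,V1,strong,35,2.8
1.0,60,V2,mild,34,2.0
1.0,60,V2,standard,35,2.4
1.0,60,V2,strong,33,2.9
1.0,70,V1,mild,22,1.0
1.0,70,V1,standard,24,3.7
1.0,70,V1,strong,23,1.0
1.0,70,V2,mild,23,1.8
1.0,70,V2,standard,22,1.2
1.0,70,V2,strong,26,1.5
0.5,40,V1,mild,42,4.6
0.5,40,V1,standard,43,4.7
0.5,40,V1,strong,41,1.8
0.5,40,V2,mild,40,6.0
0.5,40,V2,standard,39,4.3
0.5,40,V2,strong,37,3.3
0.5,50,V1,mild,25,1.5
0.5,50,V1,standard,29,3.4
0.5,50,V1,strong,24,1.5
0.5,50,V2,mild,22,2.0
0.5,50,V2,standard,26,2.2
0.5,50,V2,strong,21,2.1
0.5,60,V1,mild,20,1.0
0.5,60,V1,standard,23,1.8
0.5,60,V1,strong,21,1.2
0.5,60,V2,mild,18,1.4
0.5,60,V2,standard,20,1.6
0.5,60,V2,strong,19,1.8
0.5,70,V1,mild,15,1.3
0.5,70,V1,standard,14,1.1
0.5,70,V1,strong,17,0.8
0.5,70,V2,mild,13,1.8
0.5,70,V2,standard,12,1.2
0.5,70,V2,strong,15,1.0
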