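version,keV,level,mean_hu,sd_hu
V1,40,mild,100.2,0.40
V1,40,standard,86.6,0.35
V1,40,strong,65.6,0.31
V1,50,mild,52.4,0.32
V1,50,standard,45.3,0.22
V1,50,strong,34.3,0.28
V1,60,mild,24.3,0.09
V1,60,standard,21.0,0.13
V1,60,strong,15.5,0.19
V1,70,mild,12.5,0.10
V1,70,standard,10.6,0.08
V1,70,strong,7.7,0.12
V2,40,mild,68.5,0.20
V2,40,standard,55.1,0.27
V2,40,strong,44.6,0.41
V2,50,mild,34.3,0.10
V2,50,standard,28.1,0.14
V2,50,strong,22.7,0.21
V2,60,mild,16.6,0.04
V2,60,standard,13.6,0.07
V2,60,strong,10.9,0.10
V2,70,mild,13.1,0.04
V2,70,standard,10.6,0.05
V2,70,strong,8.1,0.08
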