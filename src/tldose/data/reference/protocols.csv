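name,scanner,kvp,ma,rotation_s,pitch,collimation,ctdi_vol_mgy
p1,GE Discovery 750 HD,80,800,0.4,0.97,32x0.625,8.89
p2,GE Discovery 750 HD,100,800,0.4,0.97,32x0.625,16.65
p3,Canon Aquilion One Vision,80,700,0.275,0.83,80x0.5,7.50
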