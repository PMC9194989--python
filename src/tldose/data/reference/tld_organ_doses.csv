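organ,protocol,mean_per_ctdi,sd_per_ctdi
active_marrow,p1,1.67,0.29
active_marrow,p2,1.81,0.29
active_marrow,p3,1.98,0.46
bladder,p1,2.16,0.25
bladder,p2,2.03,0.18
bladder,p3,2.40,0.29
bone_surface,p1,1.67,0.51
bone_surface,p2,2.78,0.31
bone_surface,p3,2.72,0.38
brain,p1,1.71,0.12
brain,p2,1.86,0.18
brain,p3,2.16,0.17
breast,p1,2.01,0.16
breast,p2,1.82,0.09
breast,p3,2.14,0.10
colon,p1,2.20,0.08
colon,p2,1.98,0.22
colon,p3,2.19,0.23
liver,p1,2.11,0.34
liver,p2,2.26,0.12
liver,p3,2.38,0.14
lung,p1,2.43,0.30
lung,p2,2.46,0.25
lung,p3,2.52,0.39
esophagus,p1,2.28,0.31
esophagus,p2,2.19,0.17
esophagus,p3,2.46,0.02
ovaries,p1,1.94,0.22
ovaries,p2,1.99,0.19
ovaries,p3,2.21,0.24
salivary_glands,p1,1.80,0.12
salivary_glands,p2,2.09,0.21
salivary_glands,p3,2.39,0.07
skin,p1,2.48,0.24
skin,p2,2.37,0.43
skin,p3,2.79,0.42
stomach,p1,2.06,0.20
stomach,p2,2.20,0.18
stomach,p3,2.28,0.23
testes,p1,2.55,0.22
testes,p2,2.34,0.37
testes,p3,2.43,0.13
thyroid,p1,2.69,0.23
thyroid,p2,2.56,0.54
thyroid,p3,3.40,0.16
heart,p1,2.36,0.14
heart,p2,2.33,0.24
heart,p3,2.65,0.06
kidney,p1,2.36,0.22
kidney,p2,2.11,0.28
kidney,p3,2.16,0.08
muscle,p1,2.12,0.28
muscle,p2,2.10,0.18
muscle,p3,2.38,0.42
pancreas,p1,2.35,0.17
pancreas,p2,2.19,0.22
pancreas,p3,2.37,0.11
prostate,p1,2.10,0.12
prostate,p2,1.98,0.06
prostate,p3,2.27,0.20
small_bowel,p1,1.94,0.20
small_bowel,p2,1.97,0.27
small_bowel,p3,2.00,0.17
spleen,p1,2.48,0.26
spleen,p2,2.10,0.17
spleen,p3,2.74,0.12
uterus,p1,1.79,0.11
uterus,p2,1.98,0.06
uterus,p3,1.94,0.16
lens,p1,1.78,0.13
lens,p2,1.79,0.22
lens,p3,2.25,0.41
spine,p1,1.92,0.28
spine,p2,1.82,0.21
spine,p3,1.83,0.66
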