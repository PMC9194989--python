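tissue,w_T,category,provenance
active_marrow,0.12,primary,ICRP 103 tissue weighting factors
colon,0.12,primary,ICRP 103 tissue weighting factors
lung,0.12,primary,ICRP 103 tissue weighting factors
stomach,0.12,primary,ICRP 103 tissue weighting factors
breast,0.12,primary,ICRP 103 tissue weighting factors
gonads,0.08,primary,ICRP 103 tissue weighting factors
bladder,0.04,primary,ICRP 103 tissue weighting factors
esophagus,0.04,primary,ICRP 103 tissue weighting factors
liver,0.04,primary,ICRP 103 tissue weighting factors
thyroid,0.04,primary,ICRP 103 tissue weighting factors
bone_surface,0.01,primary,ICRP 103 tissue weighting factors
brain,0.01,primary,ICRP 103 tissue weighting factors
salivary_glands,0.01,primary,ICRP 103 tissue weighting factors
skin,0.01,primary,ICRP 103 tissue weighting factors
heart,0.12,remainder-member,ICRP 103 remainder block (measured members)
kidney,0.12,remainder-member,ICRP 103 remainder block (measured members)
muscle,0.12,remainder-member,ICRP 103 remainder block (measured members)
pancreas,0.12,remainder-member,ICRP 103 remainder block (measured members)
prostate,0.12,remainder-member,ICRP 103 remainder block (measured members)
small_bowel,0.12,remainder-member,ICRP 103 remainder block (measured members)
spleen,0.12,remainder-member,ICRP 103 remainder block (measured members)
uterus,0.12,remainder-member,ICRP 103 remainder block (measured members)
lens,0.0,non-contributing,reported organ without an ICRP 103 weight
spine,0.0,non-contributing,reported organ without an ICRP 103 weight
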