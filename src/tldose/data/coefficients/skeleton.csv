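site,rbm_mass_g,shallow_mass_g,cellularity,def_rbm,def_shallow,provenance
legs,30.0,18.0,1.0,0.14,0.35,ICRP 70/89-style age-1 marrow masses; King et al.-style RBM DEF; ICRP 110-style adult shallow DEF
pelvis,22.0,12.0,1.0,0.17,0.42,ICRP 70/89-style age-1 marrow masses; King et al.-style RBM DEF; ICRP 110-style adult shallow DEF
rib,12.0,7.0,1.0,0.21,0.48,ICRP 70/89-style age-1 marrow masses; King et al.-style RBM DEF; ICRP 110-style adult shallow DEF
spine,42.0,20.0,1.0,0.19,0.45,ICRP 70/89-style age-1 marrow masses; King et al.-style RBM DEF; ICRP 110-style adult shallow DEF
skull,44.0,25.0,1.0,0.25,0.52,ICRP 70/89-style age-1 marrow masses; King et al.-style RBM DEF; ICRP 110-style adult shallow DEF
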