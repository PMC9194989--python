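tissue,energy_kev,mu_en_over_rho,provenance
water,10,4.944,ICRU 46-style mass energy-absorption table
water,15,1.374,ICRU 46-style mass energy-absorption table
water,20,0.5503,ICRU 46-style mass energy-absorption table
water,30,0.1557,ICRU 46-style mass energy-absorption table
water,40,0.06947,ICRU 46-style mass energy-absorption table
water,50,0.04223,ICRU 46-style mass energy-absorption table
water,60,0.03190,ICRU 46-style mass energy-absorption table
water,80,0.02597,ICRU 46-style mass energy-absorption table
water,100,0.02546,ICRU 46-style mass energy-absorption table
water,150,0.02764,ICRU 46-style mass energy-absorption table
soft_tissue,10,4.622,ICRU 46-style mass energy-absorption table
soft_tissue,15,1.272,ICRU 46-style mass energy-absorption table
soft_tissue,20,0.5070,ICRU 46-style mass energy-absorption table
soft_tissue,30,0.1438,ICRU 46-style mass energy-absorption table
soft_tissue,40,0.06474,ICRU 46-style mass energy-absorption table
soft_tissue,50,0.03987,ICRU 46-style mass energy-absorption table
soft_tissue,60,0.03051,ICRU 46-style mass energy-absorption table
soft_tissue,80,0.02530,ICRU 46-style mass energy-absorption table
soft_tissue,100,0.02501,ICRU 46-style mass energy-absorption table
soft_tissue,150,0.02732,ICRU 46-style mass energy-absorption table
red_marrow,10,4.100,ICRU 46-style mass energy-absorption table
red_marrow,15,1.133,ICRU 46-style mass energy-absorption table
red_marrow,20,0.4502,ICRU 46-style mass energy-absorption table
red_marrow,30,0.1288,ICRU 46-style mass energy-absorption table
red_marrow,40,0.05945,ICRU 46-style mass energy-absorption table
red_marrow,50,0.03778,ICRU 46-style mass energy-absorption table
red_marrow,60,0.02971,ICRU 46-style mass energy-absorption table
red_marrow,80,0.02530,ICRU 46-style mass energy-absorption table
red_marrow,100,0.02537,ICRU 46-style mass energy-absorption table
red_marrow,150,0.02791,ICRU 46-style mass energy-absorption table
yellow_marrow,10,3.270,ICRU 46-style mass energy-absorption table
yellow_marrow,15,0.9060,ICRU 46-style mass energy-absorption table
yellow_marrow,20,0.3604,ICRU 46-style mass energy-absorption table
yellow_marrow,30,0.1048,ICRU 46-style mass energy-absorption table
yellow_marrow,40,0.05066,ICRU 46-style mass energy-absorption table
yellow_marrow,50,0.03442,ICRU 46-style mass energy-absorption table
yellow_marrow,60,0.02847,ICRU 46-style mass energy-absorption table
yellow_marrow,80,0.02571,ICRU 46-style mass energy-absorption table
yellow_marrow,100,0.02616,ICRU 46-style mass energy-absorption table
yellow_marrow,150,0.02914,ICRU 46-style mass energy-absorption table
air,10,4.742,ICRU 46-style mass energy-absorption table
air,15,1.334,ICRU 46-style mass energy-absorption table
air,20,0.5389,ICRU 46-style mass energy-absorption table
air,30,0.1537,ICRU 46-style mass energy-absorption table
air,40,0.06833,ICRU 46-style mass energy-absorption table
air,50,0.04098,ICRU 46-style mass energy-absorption table
air,60,0.03041,ICRU 46-style mass energy-absorption table
air,80,0.02407,ICRU 46-style mass energy-absorption table
air,100,0.02325,ICRU 46-style mass energy-absorption table
air,150,0.02496,ICRU 46-style mass energy-absorption table
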