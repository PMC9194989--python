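material,energy_kev,mu_over_rho,density_g_cm3,provenance
Al,10,26.23,2.699,NIST XCOM-style mass attenuation table
Al,15,7.955,2.699,NIST XCOM-style mass attenuation table
Al,20,3.441,2.699,NIST XCOM-style mass attenuation table
Al,30,1.128,2.699,NIST XCOM-style mass attenuation table
Al,40,0.5685,2.699,NIST XCOM-style mass attenuation table
Al,50,0.3681,2.699,NIST XCOM-style mass attenuation table
Al,60,0.2778,2.699,NIST XCOM-style mass attenuation table
Al,80,0.2018,2.699,NIST XCOM-style mass attenuation table
Al,100,0.1704,2.699,NIST XCOM-style mass attenuation table
Al,150,0.1378,2.699,NIST XCOM-style mass attenuation table
Cu,10,215.9,8.96,NIST XCOM-style mass attenuation table
Cu,15,74.05,8.96,NIST XCOM-style mass attenuation table
Cu,20,33.79,8.96,NIST XCOM-style mass attenuation table
Cu,30,10.92,8.96,NIST XCOM-style mass attenuation table
Cu,40,4.862,8.96,NIST XCOM-style mass attenuation table
Cu,50,2.613,8.96,NIST XCOM-style mass attenuation table
Cu,60,1.593,8.96,NIST XCOM-style mass attenuation table
Cu,80,0.7630,8.96,NIST XCOM-style mass attenuation table
Cu,100,0.4584,8.96,NIST XCOM-style mass attenuation table
Cu,150,0.2217,8.96,NIST XCOM-style mass attenuation table
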