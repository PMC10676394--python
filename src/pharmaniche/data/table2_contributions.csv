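factor,long_name,percent_contribution,permutation_importance,main_factor
prec-10,Precipitation of October,37.3,1.4,1
srad-10,Solar Radiation of October,20.1,3.2,1
prec-11,Precipitation of November,9.9,4.6,1
bio-5,Max Temperature of Warmest Month,7.1,20.9,1
su_sym90,Soil Unit Symbol (FAO-90),5.7,0.6,1
bio-3,Isothermality,5.7,1.6,0
prec-5,Precipitation of May,4.4,5.7,1
awc_class,Soil available water capacity class,3.5,1.0,1
bio-14,Precipitation of Driest Month,2.2,0.7,1
elev,Altitude,2.1,18.4,1
t_oc,Topsoil organic carbon,0.9,0.2,0
prec-4,Precipitation of April,0.4,39.7,1
bio-6,Min Temperature of Coldest Month,0.3,1.4,0
t_sand,Topsoil sand fraction,0.2,0.4,0
t_clay,Topsoil clay fraction,0.2,0.2,0
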