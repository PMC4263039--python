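sex,band_start,band_width,population,l_comparator,T_comparator,e_comparator,l_intervention,T_intervention,e_intervention
male,25,10,37654,37654,1515469,40.2,37654,1541953,41.0
male,35,10,116478,36837,1143011,31.0,36846,1169453,31.7
male,45,10,176800,34930,784172,22.4,34986,810293,23.2
male,55,10,170466,31632,451359,14.3,31889,475917,14.9
male,65,10,115191,23962,173390,7.2,24859,192175,7.7
male,75,-1,57486,7685,15155,2.0,9357,21094,2.3
female,25,10,70088,70088,3201030,45.7,70088,3273923,46.7
female,35,10,208972,68531,2507937,36.6,68544,2580762,37.7
female,45,10,284081,66330,1833631,27.6,66400,1906039,28.7
female,55,10,242488,63398,1184986,18.7,63693,1255573,19.7
female,65,10,173947,55288,591552,10.7,56402,655097,11.6
female,75,-1,114595,33421,148007,4.4,36533,190422,5.2
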