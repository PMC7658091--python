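name,lat,lon,altitude_m
Zurich,47.38,8.52,408
St. Gallen,47.43,9.39,674
Chur,46.85,9.52,593
Lugano,46.02,8.95,275
Sion,46.23,7.35,515
Lausanne,46.54,6.58,495
Delemont,47.37,7.34,435
Basel,47.55,7.57,260
Aarau,47.39,8.05,384
Bern,46.95,7.44,542
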