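scenario_id,period,pct_suitable,pct_highly_suitable,pct_one_gen,pct_two_gen
reference,1981-2010,23.0,0.3,33.2,0.3
year,2015,43.9,0.7,44.6,1.1
year,2016,31.3,0.1,38.4,0.7
year,2017,37.9,4.0,43.1,1.1
year,2018,49.1,8.4,50.1,6.0
year,2019,39.5,3.2,43.0,1.0
RCP3PD,2020-2049,32.1,4.9,43.1,1.0
RCP3PD,2045-2074,36.6,8.3,45.3,1.5
RCP3PD,2070-2099,37.3,8.7,45.5,1.6
A1B,2020-2049,32.6,5.2,43.7,1.1
A1B,2045-2074,43.5,20.5,52.3,7.5
A1B,2070-2099,52.3,32.5,59.6,26.7
A2,2020-2049,41.8,4.5,42.6,0.9
A2,2045-2074,52.1,19.9,51.9,7.0
A2,2070-2099,63.6,36.9,63.5,34.8
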