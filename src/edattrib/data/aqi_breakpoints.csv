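pollutant,aqi_low,aqi_high,conc_low,conc_high,unit
pm10,0,50,0,54,ug/m3
pm10,51,100,55,154,ug/m3
pm10,101,150,155,254,ug/m3
pm10,151,200,255,354,ug/m3
pm10,201,300,355,424,ug/m3
pm10,301,400,425,504,ug/m3
pm10,401,500,505,604,ug/m3
so2,0,50,0,35,ppb
so2,51,100,36,75,ppb
so2,101,150,76,185,ppb
so2,151,200,186,304,ppb
so2,201,300,305,604,ppb
so2,301,400,605,804,ppb
so2,401,500,805,1004,ppb
co,0,50,0.0,4.4,ppm
co,51,100,4.5,9.4,ppm
co,101,150,9.5,12.4,ppm
co,151,200,12.5,15.4,ppm
co,201,300,15.5,30.4,ppm
co,301,400,30.5,40.4,ppm
co,401,500,40.5,50.4,ppm
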