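#machine,synergy
#tpr2010,0.687
#entrance
field_size_cm,1.5,6.5,11.5,16.5,21.5,26.5,31.5
5,0.993,0.996,0.997,0.997,0.998,0.998,1.000
10,0.987,0.995,0.997,0.998,0.999,0.999,1.000
15,0.981,0.993,0.996,0.998,0.999,0.998,1.000
20,0.978,0.992,0.996,0.999,1.000,1.000,1.000
#exit
field_size_cm,6.5,11.5,16.5,21.5,26.5,31.5
5,1.000,0.993,0.987,0.984,0.977,0.975
10,0.988,0.987,0.986,0.985,0.982,0.983
15,0.978,0.978,0.976,0.971,0.972,0.971
20,0.971,0.968,0.966,0.965,0.962,0.960
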