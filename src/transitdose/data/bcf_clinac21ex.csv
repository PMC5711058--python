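#machine,clinac21ex
#tpr2010,0.669
#entrance
field_size_cm,1.5,6.5,11.5,16.5,21.5,26.5,31.5
5,0.991,0.995,0.998,0.998,0.999,0.999,1.000
10,0.985,0.994,0.998,0.999,0.999,1.000,1.000
15,0.978,0.991,0.997,0.999,0.999,1.000,1.000
20,0.972,0.990,0.996,0.999,0.999,1.001,1.000
#exit
field_size_cm,6.5,11.5,16.5,21.5,26.5,31.5
5,0.995,0.991,0.984,0.976,0.970,0.972
10,0.987,0.983,0.980,0.973,0.970,0.960
15,0.983,0.978,0.974,0.972,0.968,0.965
20,0.981,0.972,0.973,0.969,0.965,0.963
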