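transducer,f250,f500,f1000,f2000,f4000,f8000
ER-3A,14.5,6.0,0,2.5,0,-3.5
HearTest v1,11.8,9.5,6,2.3,6.7,16.2
HearTest v2,1.8,-5.5,1,7.3,13.7,13.7
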