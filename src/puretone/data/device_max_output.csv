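device,channel,f250,f500,f1000,f2000,f4000,f8000
iPhone XR,L,85.1,93.5,107.2,112.8,106,108.8
iPhone XR,R,84.9,93.4,107.3,113,106.1,108.7
iPhone 10,L,83.4,94.6,107.8,113.5,105.7,108.6
iPhone 10,R,83.5,94.1,108.1,113.2,105.8,108.2
iPhone 8,L,83.1,93.3,107.3,112.8,106.4,108.5
iPhone 8,R,83.3,93.3,107.2,112.7,106.1,108.9
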