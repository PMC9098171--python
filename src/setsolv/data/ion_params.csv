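ion,charge,amplitude
Li+,1,51
Na+,1,72
K+,1,64
Cs+,1,55
Cl-,-1,94
Br-,-1,66
I-,-1,55
NO3-,-1,56
SCN-,-1,54
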