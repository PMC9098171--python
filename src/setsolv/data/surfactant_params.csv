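surfactant,A,B
MEGA8,-29.42,1.24
MEGA9,-30.03,1.32
GLUCO8,-29.04,1.29
C12E6,-52.32,2.09
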