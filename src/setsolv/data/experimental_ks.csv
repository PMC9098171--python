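surfactant,cation,anion,ks,source_flag
MEGA8,Li+,Cl-,0.33,monovalent
MEGA9,Li+,Cl-,0.36,monovalent
GLUCO8,Li+,Cl-,0.43,monovalent
C12E6,Li+,Cl-,0.53,monovalent
MEGA8,Na+,F-,0.87,excluded
MEGA9,Na+,F-,1.01,excluded
MEGA8,Na+,Cl-,0.53,monovalent
MEGA9,Na+,Cl-,0.56,monovalent
GLUCO8,Na+,Cl-,0.57,monovalent
C12E6,Na+,Cl-,0.81,monovalent
MEGA8,Na+,Br-,0.37,monovalent
MEGA9,Na+,Br-,0.45,monovalent
MEGA8,Na+,NO3-,0.30,monovalent
MEGA9,Na+,NO3-,0.37,monovalent
MEGA8,Na+,I-,0.35,monovalent
MEGA9,Na+,I-,0.35,monovalent
MEGA8,Na+,SCN-,0.29,monovalent
MEGA8,K+,Cl-,0.47,monovalent
MEGA9,K+,Cl-,0.56,monovalent
C12E6,K+,Cl-,0.69,monovalent
MEGA8,K+,Br-,0.34,monovalent
MEGA9,K+,Br-,0.38,monovalent
C12E6,K+,Br-,0.48,monovalent
MEGA8,K+,I-,0.26,monovalent
MEGA9,K+,I-,0.30,monovalent
C12E6,K+,I-,0.30,monovalent
MEGA8,Cs+,Cl-,0.39,monovalent
MEGA8,Ca2+,Cl-,0.67,divalent
MEGA8,Na+,HPO4^2-,1.20,divalent
MEGA8,Na+,SO3^2-,1.38,divalent
MEGA8,Na+,CO3^2-,1.53,divalent
MEGA9,Na+,CO3^2-,1.79,divalent
MEGA8,Na+,SO4^2-,1.59,divalent
MEGA9,Na+,SO4^2-,1.85,divalent
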