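# Approximate coarse-grained representation of n-octanoyl-N-methylglucamine.
# Bead sequence, r0 and theta0 are approximations chosen so that every pair of
# bead types in a surfactant+water system resolves in the shipped interaction
# table; they are placeholders for a properly derived fragmentation.
name: MEGA8
beads: [T, C2, C2, AM3, OHp, OH]
bonds:
  - {i: 0, j: 1, r0: 0.5}
  - {i: 1, j: 2, r0: 0.5}
  - {i: 2, j: 3, r0: 0.5}
  - {i: 3, j: 4, r0: 0.5}
  - {i: 4, j: 5, r0: 0.5}
angles:
  - {i: 0, j: 1, k: 2, theta0_deg: 180.0}
  - {i: 1, j: 2, k: 3, theta0_deg: 180.0}
  - {i: 2, j: 3, k: 4, theta0_deg: 180.0}
  - {i: 3, j: 4, k: 5, theta0_deg: 180.0}
head_beads: [AM3, OHp, OH]
tail_beads: [T, C2]
molar_mass: 293.4
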