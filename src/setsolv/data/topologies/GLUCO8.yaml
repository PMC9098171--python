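# Approximate coarse-grained representation of n-octyl glucopyranoside.
# T2 beads carry the octyl tail because the shipped interaction table has no
# C2-OH2 / T-ACp / T-OH2 cross terms; see MEGA8.yaml for the status of these
# approximations.
name: GLUCO8
beads: [T2, T2, ACp, OHp, OH2]
bonds:
  - {i: 0, j: 1, r0: 0.5}
  - {i: 1, j: 2, r0: 0.5}
  - {i: 2, j: 3, r0: 0.5}
  - {i: 3, j: 4, r0: 0.5}
angles:
  - {i: 0, j: 1, k: 2, theta0_deg: 180.0}
  - {i: 1, j: 2, k: 3, theta0_deg: 180.0}
  - {i: 2, j: 3, k: 4, theta0_deg: 180.0}
head_beads: [ACp, OHp, OH2]
tail_beads: [T2]
molar_mass: 292.4
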