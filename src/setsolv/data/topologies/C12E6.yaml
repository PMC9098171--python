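# Approximate coarse-grained representation of hexaethylene glycol monododecyl
# ether; each EO bead stands for two ethylene-oxide repeats. See MEGA8.yaml for
# the status of these approximations.
name: C12E6
beads: [T, C2, C2, C2, EO, EO, EO, OH]
bonds:
  - {i: 0, j: 1, r0: 0.5}
  - {i: 1, j: 2, r0: 0.5}
  - {i: 2, j: 3, r0: 0.5}
  - {i: 3, j: 4, r0: 0.5}
  - {i: 4, j: 5, r0: 0.5}
  - {i: 5, j: 6, r0: 0.5}
  - {i: 6, j: 7, r0: 0.5}
angles:
  - {i: 0, j: 1, k: 2, theta0_deg: 180.0}
  - {i: 1, j: 2, k: 3, theta0_deg: 180.0}
  - {i: 2, j: 3, k: 4, theta0_deg: 180.0}
  - {i: 3, j: 4, k: 5, theta0_deg: 180.0}
  - {i: 4, j: 5, k: 6, theta0_deg: 180.0}
  - {i: 5, j: 6, k: 7, theta0_deg: 180.0}
head_beads: [EO, OH]
tail_beads: [T, C2]
molar_mass: 450.6
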