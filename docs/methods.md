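# Methods

## Model overview

`setsolv` implements a dissipative particle dynamics (DPD) model of nonionic
surfactants in water with added monovalent salt, together with the analysis
chain that turns trajectories into critical micelle concentrations (CMC) and
the statistical model that links salting-out behaviour to ion–surfactant
repulsion parameters.

The working hypothesis of the parameterization is that the log-linear
Setschenow dependence of the CMC on salt concentration,

    ln(CMC / CMC0) = −k_s · C_salt,

is reproduced by the DPD model, and that the simulated coefficient k_s is
controlled almost entirely by the short-range repulsion amplitudes between
the ion beads and the hydrophobic tail beads. Matching simulated to
experimental k_s therefore pins those amplitudes, ion by ion.

## DPD interactions

Beads interact through the standard linear soft repulsion with per-pair
range: `F(r) = a_ij (1 − r/R_ij) r̂` for `r < R_ij`, with the corresponding
energy `(a_ij R_ij / 2)(1 − r/R_ij)²`. Amplitudes are in kBT, lengths in the
DPD unit r_c (the water–water range). The packaged interaction table covers
ten bead species (water W; tails T, T2, C2; heads AM3, OH, OH′, OH2, AC′;
ethylene oxide EO) with 10 self and 30 cross terms. Absent cross terms raise
an error at system construction: the package never invents parameters.

Bonds are harmonic, `½ k_b (r − r_0)²` with `k_b = 150 kBT/r_c²`; angles are
harmonic in the angle, `½ k_a (θ − θ_0)²` with `k_a = 5 kBT/rad²`. The angle
gradient uses a guarded small-sine branch so collinear triples (including the
θ₀ = π equilibrium itself) stay finite. Equilibrium values `r_0` and `θ_0`
are per-topology configuration data; the shipped surfactant topologies use
r_0 = 0.5 r_c and θ_0 = 180° as placeholders, because the bead-level
geometry of the four packaged surfactants is not derivable from first
principles here. The topology YAMLs are explicitly labelled approximate;
every quantitative result in the package (pressure, unit mapping, parameter
tables) is independent of them.

Salt ions are charged water beads: an ion bead carries valence ±1 and
inherits every W interaction unless an explicit ion–tail override is set.
Override cutoffs inherit the corresponding W–tail range; only amplitudes are
ion-specific. The screened amplitude window [35, 150] kBT is enforced unless
explicitly widened.

## Thermostat, integration, observables

The DPD thermostat applies pairwise dissipative `−γ w²(r) (r̂·v) r̂` and
random `σ w(r) θ_ij r̂ / √Δt` forces with `w(r) = 1 − r` on the unit range,
`σ² = 2γ kBT`, γ = 4.5 and Δt = 0.01 by default. The per-pair noise θ_ij is
a counter-based Gaussian: a hash of the unordered pair indices and a
per-step salt. This makes forces independent of iteration order (cell list
and all-pairs loops agree to 1e-10) and trajectories bitwise reproducible
given a seed. Integration is velocity Verlet with thermostat forces
evaluated at half-step velocities; a per-step displacement guard (0.5 r_c)
aborts unstable runs with advice to reduce Δt.

Temperature is `2·KE/(3N−3)`; pressure is `(N·kBT_inst + W/3)/V` with the
virial W accumulated from conservative and bonded forces only (thermostat
contributions average to the kinetic part; electrostatic virial is not
included in the reported pressure — charged runs here are NVT). Constant
pressure uses Berendsen isotropic rescaling toward the target (default
23.7, the reduced pressure of pure DPD water at a = 25, ρr_c³ = 3, which the
NVT engine reproduces within 0.1).

At Δt = 0.01 the measured kinetic temperature of pure water sits within
0.5% of the nominal kBT = 1 — comfortably inside the 2% discretization
budget the tests enforce.

## Electrostatics

Charges are Slater-smeared: the pair energy
`u(r) = (Γ q_i q_j / 4πr)[1 − (1 + β*r) e^(−2β*r)]` is finite at contact
(`u(0) = Γ q_i q_j β*/4π`) and has the bare Coulomb tail. Defaults:
Γ = 15.94, β* = 0.929 r_c⁻¹. Periodicity is handled by point-charge Ewald
(real-space cutoff 3.0 r_c, reciprocal cutoff 5 r_c⁻¹ on the wave-vector
magnitude |k| = 2π|n|/L, splitting α = 1.0 r_c⁻¹) plus the short-range
smearing correction `u_slater − u_coulomb` truncated with the real-space
part. Note the correction decays as e^(−2β*r) ≈ 4e-3 at 3 r_c, so sub-1e-4
energy comparisons (e.g. against direct lattice sums) need a larger
real-space cutoff; the tests use 7 r_c boxes for that purpose. α is free:
the energy is α-independent to better than 1e-5 once both cutoffs resolve
the split.

## Unit mapping

One water bead is N_m = 2 water molecules. With molar volume
V_m = 18×10⁻⁶ m³/mol and ρr_c³ = 3, one mole of r_c-cubes is
N_A r_c³ = ρr_c³·N_m·V_m ≈ 0.108 L and r_c = 5.64 Å. Concentration
conversions (salt pairs per box, CMC in mol/L) use the 3-significant-figure
working constant 0.108 L/mol so that printed-precision arithmetic (e.g.
1 M in an L = 30 box ↔ 2916 ion pairs) is exact; the unrounded value is
available from `MappingContext`.

The electrostatic coupling Γ = e²/(kB T ε₀ ε_r r_c) evaluates to 15.96 with
the rounded V_m above and to 15.94 with the measured molar volume of water
at 298 K (18.07 cm³/mol, i.e. r_c = 5.647 Å). The package treats 15.94 as
the canonical value (it is self-consistent with the physical density of
water); the 0.1% discrepancy is below anything the model resolves.

## Micelle analysis

Aggregates are identified per frame by single-linkage clustering: two
surfactant molecules join when any pair of their tail beads is within the
contact cutoff (default 1.0 r_c) under minimum image. Tail association
defines the micelle core; the bead set and cutoff are configuration.
Pooling sizes over post-equilibration frames (default discard: the first
1/8 of the run, the production equilibration fraction scaled to run length)
gives the population distribution P(N) on a dense size axis, optionally
smoothed by a short moving average (window 3) before minimum finding.

N_cut is the minimum of smoothed P(N) strictly between the smallest-N and
largest-N modes, ties broken toward smaller N; a distribution with no
interior minimum falls back to N_cut = 10 with a warning. The CMC is the
mean number of molecules in aggregates with N < N_cut (monomers plus
submicellar aggregates) converted to mol/L; runs at several loadings are
averaged. Both molecule weighting (default) and aggregate weighting of
P(N) are available.

## Setschenow model and fitting

`fit_ks` is ordinary least squares of ln(CMC/CMC0) on C_salt with a free
(reported) intercept; k_s = −slope, so positive k_s means salting out.

The separable model is `k_s = A(1/a₊ + 1/a₋) + B` with per-surfactant
constants A (M⁻¹·kBT, negative for all fitted surfactants) and B (M⁻¹),
and per-ion tail amplitudes a₊, a₋ (kBT). The functional form was validated
against the packaged reference comparison table before being built upon: it
reproduces all 25 monovalent calculated coefficients within ±0.02 (the
rounding of the printed inputs) and the four spotlight entries exactly at
two decimals. Its additivity means a salt is the sum of its ions' effects,
which is what makes the parameters transferable across surfactants.

Fitting is two-stage, mirroring how the packaged tables were built:
(A, B) per surfactant by linear least squares at fixed ion amplitudes, then
ion amplitudes jointly across all surfactants by bounded trust-region
nonlinear least squares (bounds default to the screening window [35, 150]).
A spreadsheet-style generalized-reduced-gradient optimizer would find the
same minimum; only the minimizer matters.

**Identifiability.** Because k_s depends on the ions only through
1/a₊ + 1/a₋, shifting all inverse cation amplitudes by +δ and all inverse
anion amplitudes by −δ changes nothing observable: individual amplitudes
are identified only up to this one-parameter gauge, while the sums, and the
ordering within each charge group, are fully identified. `fit_ion_amplitudes`
therefore accepts pinned reference ions (`fixed=`); without pinning it
returns one representative of the optimal family (whichever the solver
reaches from its start), which is also what the original spreadsheet fit
did. Ions supported by a single measurement (Cs⁺, SCN⁻ in the packaged
data) are flagged weakly identified.

Fluoride rows ship flagged `excluded` (no finite tail amplitude in the
screened window describes them); divalent-salt rows ship flagged `divalent`
and are out of the fitting scope.

## Synthetic data

Micelle fixtures are geometric, not physical: planted micelles put every
tail bead inside a ball of half the contact cutoff around the micelle
center (a connectivity clique, so single linkage provably recovers the
planted partition), head beads on a shell outside it, and monomers at least
3 r_c from any micelle. They validate the analysis chain, not the engine —
passing fixtures says nothing about whether the dynamics micellizes, which
is checked separately by a small self-assembly run. Setschenow fixtures
emit CMC series that follow the log-linear law exactly from a planted
separable model, with optional lognormal noise on the CMC values; with zero
noise every fitting stage must invert them exactly, which is the round-trip
the tests enforce.

## Problem sizes and defaults used in validation

The validation suite runs desk-scale systems chosen to keep each check
statistically meaningful at interactive cost: pure-water boxes of L = 5 and
L = 10 r_c (375 / 3,000 beads) with 5×10³–2.5×10⁴ steps for thermostat and
equation-of-state checks, a 30-molecule amphiphile box (L = 8, 1,536 beads,
5×10⁴ steps) for qualitative self-assembly, 8-charge toys for electrostatic
oracles, and 20-seed fixture families for the analysis stages. Production
runs of the original parameterization study (81,000 beads, 4×10⁶ steps,
full k_s response surfaces) are outside the package's validation scope,
though the engine accepts such configurations.

## Known limitations

- The shipped surfactant topologies are structural placeholders; quantitative
  CMC predictions for the named surfactants would require properly derived
  fragmentations and r_0/θ_0 values.
- The reported pressure omits the electrostatic virial; NPT runs with salt
  are therefore not supported (NVT is the default and reference mode).
- The Ewald reciprocal sum is a dense k-vector loop — appropriate for the
  desk-scale charged systems used here, not tuned for thousands of charges.
- Ion amplitudes from k_s data alone carry the gauge freedom described
  above; comparisons of absolute amplitudes across studies must fix the
  same reference ion.
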