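# Methods

This note documents the models implemented in `emultrans`, the choices made
where the underlying methods leave latitude, and what the test suite's
scaled-down computations do and do not demonstrate.

## Coarse-grained model

All quantities are in reduced Lennard-Jones units: bead diameter sigma,
bead mass m, thermal energy epsilon = kB T, time tau = sigma sqrt(m/eps).
Five bead species exist (W, O, Hs, Hd, T).  Nonbonded pairs interact via
the 12-6 LJ potential U(r) = 4 eps_ij [(sigma/r)^12 - (sigma/r)^6] with
cutoff 3.0 sigma, or via the WCA form (LJ truncated at 2^(1/6) sigma and
shifted by eps) for pairs that must be purely repulsive -- most importantly
W-O, which makes the two solvents immiscible and produces the slab
interface.  The interaction table (see `default_interaction_matrix`):
same-species 1.0; Hs-W 1.9 (short) / 1.1 (long); Hs-Hd 3.6 (short) /
0.225 (long); Hs-O = Hs-T = T-W = 0.2; Hd-W = Hd-O = Hd-T = T-O = 0.9.
The two Hs-Hd values encode the relative hydrophilic strength of a
single-bead versus a five-bead (PEO-like) headgroup; the two Hs-W values
give the two architectures comparable interfacial coverage.

*LJ tail*: the energy is shifted so U(r_cut) = 0; forces are the exact
negative gradient of the unshifted form.  NVT observables are insensitive
to the shift; it only prevents energy jumps at the cutoff.

*Bonds*: FENE springs with the Kremer-Grest constants k = 30 eps/sigma^2,
R0 = 1.5 sigma, combined with a unit-epsilon WCA core; the combined bond
potential has its minimum at 0.9609 sigma.  Bonded pairs are excluded from
the nonbonded sum.  A bond reaching R0 aborts the run with a diagnostic
rather than silently clamping.

*Length mapping*: one water bead represents five water molecules of total
volume v_w = 0.15 nm^3; sigma maps onto the diameter of the equivalent
sphere, l_u = (6 v_w / pi)^(1/3) = 0.659 nm.  With the experimental area
per adsorbed surfactant A_s = 0.5 nm^2, the interfacial saturation count
N_s = 2 L_x L_y l_u^2 / A_s gives 2253 three-bead chains for the
36 x 36 sigma cross-section; the seven-bead count (966) preserves the
surfactant bead concentration c_s = n_s N_s / V = 0.048 sigma^-3.

## Integration

Velocity Verlet with dt = 0.005 tau coupled to a single Nose-Hoover
thermostat at T = 1 (Martyna-style quarter-kick splitting around the
position update).  The coupling time is not dictated by the model; the
default 0.5 tau holds the mean kinetic temperature within ~1% on the test
fixtures.  Setting the coupling time to zero recovers symplectic NVE
velocity Verlet, which the tests use for energy-conservation checks
(relative drift < 1e-3 over 1e5 steps on a 500-bead water/oil mixture).
The stiff FENE+WCA bond core is marginally resolved at dt = 0.005 tau, so
bonded systems conserve NVE energy only to ~1e-3 per 1e5 steps at the
production time step (the error vanishes at dt = 0.00125, and the jitted
integrator matches a plain-python velocity-Verlet reference bit-for-bit
at tolerance 1e-8); production runs are thermostatted, so this affects
none of the reported observables.

Pair sums run over a half Verlet list with 0.3 sigma skin, rebuilt when
any bead moves more than half the skin.  The list comes from a cell grid
when the box admits at least three cells per dimension, and from a
z-sorted sweep otherwise (slab boxes prune most candidates by the z gate);
both paths produce the identical pair set, which the tests verify against
a brute-force O(N^2) oracle.  Velocities carry across stage boundaries of
the equilibration schedule (rethermalizing would discard equilibrated
kinetic state for no benefit at fixed T).

Degenerate inputs (0 or 1 bead, empty stages) integrate trivially.

## Equilibration protocol

Four stages: (1) demix the liquids for 1e6 steps with all solute species
frozen; (2) homogenize the surfactant for 1e7 steps with every {T, Hs} x
{W, O} strength raised to eps; (3) form the decorated interface for
3.5e7 steps with the full table except Hd-O and T-O set to WCA, which
confines the dye to the aqueous phase; (4) production for 2e8 steps with
the full table.  `equilibration_schedule` returns exactly these counts;
a `steps_scale` argument shrinks them proportionally for reduced systems.

## Trajectory analysis

*Interfaces* are the two maxima of the Hs z-density histogram (0.5 sigma
bins), one per half-box, with a fallback to the water/oil density crossing
when no surfactant is present or the Hs profile is flat (flagged by a
warning).  On strongly downscaled systems the interfacial layer holds few
chains and micellar Hs peaks can rival it, so the simulation-study code
passes the known slab geometry explicitly.

*Phase assignment* uses the head bead (Hd for dye, Hs for surfactant):
the headgroup determines an amphiphile's solubility.  Molecules within
3 sigma of either interface are labeled interfacial, matching the margin
used to keep detected micelles away from the interface.

*Micelles*: DBSCAN (eps = 1.3 sigma, min_samples = 4 by default) over the
O/T/Hs/Hd beads in the bulk aqueous phase, with a precomputed periodic
distance matrix.  eps sits just above the first-neighbor shell at density
0.66 sigma^-3.  Cluster centers use per-axis circular means; the micelle
radius R_mic is defined as sqrt(5/3) R_g, the radius of the uniform sphere
with the cluster's gyration radius (the underlying experiments leave
R_mic operational, so the package fixes a reproducible convention).

*Concentration difference*: dc = (dye molecules per unit water volume) -
(per unit oil volume), with fixed half-box phase volumes minus the
3-sigma interfacial shells; dye inside the shells counts toward neither
phase.  The normalized series dc~ is anchored to 1 at the first analyzed
snapshot and 0 at the last, and fitted with exp(-t/lambda).

## Exchange kinetics and permeability

Units: diameters in um, times in min, permeability in m/s.  Droplet-size
bins default to equal-count quartiles (the binning rule is not dictated by
the data model; quartiles keep per-bin statistics balanced).  The
two-timescale model is dC(t) = A (e^(-t/lambda2) - e^(-t/lambda1)) with
lambda2 > lambda1: it rises from zero on the uptake scale, peaks at
t_max = lambda1 lambda2 / (lambda2 - lambda1) ln(lambda2/lambda1), and
relaxes on the exchange scale.  Because the least-squares surface is
multimodal in (lambda1, lambda2), the fitter multi-starts from a
log-spaced timescale grid.  Permeability inverts lambda = lambda0 + d/(6P)
(sphere V/S = d/6): P = 1e-6 m per um / (360 s per min x slope).

## FLIM model

Decays are modeled over the 25 ns window of 40 MHz pulsed excitation with
periodic wrap of tails that outlast the window.  With the default
parametric Gaussian IRF (fwhm 0.2 ns, arrival 1.0 ns -- the instrument
response is rarely distributed with published data, and a Gaussian of the
detector's nominal width is standard practice) the reconvolution uses the
closed-form exponential-Gaussian expression; a measured IRF histogram is
applied by circular FFT convolution instead.  Fits are least squares with
Poisson weights sqrt(max(counts, 1)); the reduced Pearson chi^2 is
evaluated over bins whose expectation is at least 5 (the near-empty tail
would otherwise deflate it), and fits with chi^2 < 1.5 are accepted.
Histograms need 1e4 photons to be fit-eligible.  The Forster-Hoffmann
calibration tau = k eta^x is a log-log least-squares fit, exact for two
anchors; the two-anchor calibration built from the pure-oil (0.52 ns,
6 mPa s) and micellar (1.28 ns, 55 mPa s) measurements gives x = 0.407
(inverse exponent 2.46) and reproduces the measured local viscosities
(15, 25, 28 mPa s) from the amplitude-weighted lifetimes to within a
rounding unit.

## Synthetic-data conditions

The emulsion scenario defaults are the study conditions: lognormal droplet
diameters (median 7.8 um, log-sd 0.32) whose equal-count quartiles average
about 5, 7, 9 and 11 um; permeability 1e-10 m/s with a 50 min offset in
lambda(d); two-timescale constants 200 min (uptake) and 5400 min
(exchange), the values measured at 1% anionic surfactant; multiplicative
Gaussian intensity noise (5% default) for concentrations and Poisson
counting noise for photons.  Generators are deterministic given a seed.
The generators emulate the statistical structure of segmented-image
droplet tables and TCSPC histograms, not raw images; conclusions about
segmentation or detector artifacts are out of reach of these tests.

## Scaled-down simulation study

The production systems (92378 beads, 2e8 production steps, three runs per
architecture) report dye-transfer decay constants lambda_short = 1.8e7 and
lambda_long = 7.7e6 steps.  That computation is far beyond a test suite,
so the package's study runs an 8 x 8 x 24 sigma slab (~1000 beads,
density and c_s preserved, 16 dye molecules as a statistical floor --
volume scaling alone would leave a single dye) for a 2000-step soft start
at dt/5, 5e3 dye-blocked relaxation steps and 8e4 production steps per
seed, three seeds per architecture.  The starting state has surfactant
pre-adsorbed at both interfaces and the dye on the water side in contact
with an interface (experimentally the dye arrives micelle-borne at the
droplet surface); starting the dye in the bulk instead makes the run
outcome hinge on whether the dye aggregate happens to diffuse to an
interface within the short window, which is aggregate-transport noise,
not the crossing physics under test.

At this scale the interface-to-volume ratio is ~7x the production value,
so the water-minus-oil concentration difference conflates two effects:
dye adsorbing *onto* the interface (fast for the short headgroup, whose
Hs-Hd attraction is 16x stronger) and dye crossing *into* the oil.  The
desk observables therefore separate them: the oil-phase dye fraction
at the end of production measures trans-interface transport (the
quantity lambda measures at full scale), and the interfacial dye excess
in the z-profile measures accumulation at the interface.  The study
passes when the long-headgroup system shows faster oil uptake in at
least two of three seeds and the short-headgroup system shows the
pronounced interfacial dye peak.  These runs demonstrate the mechanism
(headgroup-controlled interfacial crossing), not the full-scale decay
constants; the full protocol and step counts remain available through
`equilibration_schedule` and `run_simulation` for production hardware.

## Known limitations

- The engine is a correctness-first reference implementation (single
  core, numba-jitted); it is not throughput-competitive with production
  MD codes and is intended for reduced systems and testing.
- Interface detection from surfactant maxima degrades at very low
  interfacial coverage (micellar peaks compete); pass explicit interface
  positions in that regime.
- The FLIM module fits decay histograms; pixel-wise image construction
  and phasor analysis are out of scope.
- Concentration inputs to the kinetics module must be extinction-corrected
  upstream; correction factors are instrument-specific user inputs.
- Electrostatics, solvent shape anisotropy, and chemically specific
  (MARTINI-type) force fields are deliberately outside the model.
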