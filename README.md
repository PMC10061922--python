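# emultrans

Surfactant-mediated transport of lipophilic solutes in oil-in-water
emulsions: coarse-grained simulation, trajectory analysis, exchange
kinetics, and lifetime-based viscometry in one package.

## The problem

Emulsions are widely used as carriers for lipophilic (poorly
water-soluble) solutes such as drugs.  A solute loaded into the continuous
aqueous phase of an oil-in-water emulsion partitions into micelles, is
carried to the droplets, and must cross the surfactant-decorated oil-water
interface.  Which step limits the transport -- micellar diffusion through
the water, or crossing of the interface itself -- depends on the surfactant,
and the difference can stretch equilibration from hours to days.
`emultrans` implements the computational chain used to dissect this
process for a fluorescent molecular-rotor probe (a BODIPY dye with a
C12 tail) acting as a proxy solute:

1. **Coarse-grained molecular dynamics** (`cg_system`, `md_engine`): a
   bead-spring model of water (W), oil (O), surfactant (headgroup Hs +
   tail T) and dye (headgroup Hd + tail T) in reduced Lennard-Jones units.
   Solvent pairs interact via a 12-6 LJ potential (cutoff 3.0 sigma), the
   immiscible W-O pair via the purely repulsive WCA potential, and chains
   are bonded with Kremer-Grest FENE springs (k = 30, R0 = 1.5 sigma).
   The slab box (36 x 36 x 108 sigma at density 0.66 sigma^-3) holds two
   interfaces saturated by N_s = 2 L_x L_y l_u^2 / A_s surfactants;
   integration is velocity Verlet with a Nose-Hoover thermostat at T = 1,
   dt = 0.005 tau, after a four-stage equilibration protocol.  Two
   surfactant architectures are compared: a short one-bead headgroup
   (strong head-head attraction to the dye, eps = 3.6) and a long
   five-bead headgroup (weak attraction, eps = 0.225).
2. **Trajectory analysis** (`traj_analysis`): interface location from the
   surfactant-density maxima, per-molecule phase assignment with a
   3-sigma interfacial margin, DBSCAN micelle detection with periodic
   distances, the water/oil dye concentration difference
   dc~(t) with its exponential decay time, and z/radial density profiles.
3. **Exchange kinetics** (`transport_kinetics`): droplet-size binning,
   the single-exponential exchange fit
   dc(t) = dc_inf + (dc_0 - dc_inf) e^(-t/lambda), master-curve collapse,
   the two-timescale uptake/exchange model
   dC(t) = A (e^(-t/lambda2) - e^(-t/lambda1)), and permeability from
   lambda = V/(S P) = lambda_0 + d/(6P), plus the diffusion-limited
   prediction P = K D_m / l with Stokes-Einstein D_m.
4. **FLIM viscometry** (`flim`): TCSPC decay histograms fitted by
   n-exponential reconvolution with the instrument response (Poisson
   weights, reduced chi^2 < 1.5 acceptance), condensed into the
   amplitude-weighted lifetime <tau> = sum(A_i tau_i)/sum(A_i) and mapped
   to a local viscosity through the Forster-Hoffmann power law
   tau = k eta^x.
5. **Synthetic data** (`synthetic_data`): deterministic generators for
   droplet concentration tables, photon-count decays and scaled-down MD
   systems, so the whole chain is testable end to end.

## Worked example

```python
import numpy as np
from emultrans import flim, transport_kinetics as tk
from emultrans.cg_system import SystemComposition, surfactant_count
from emultrans.synthetic_data import EmulsionScenario, generate_droplet_records

# --- composition of the production simulation box -----------------------
print(surfactant_count((36, 36)), surfactant_count((36, 36), surfactant_kind="long"))
print(SystemComposition().total_beads)

# --- droplet kinetics: size-binned exponential fits -> permeability -----
scen = EmulsionScenario(n_droplets=400, noise=0.03, seed=32)
df = generate_droplet_records(scen, np.geomspace(5, 5000, 30))
bins = tk.bin_by_droplet_size(df, n_bins=4)
fits = [tk.fit_eq2(b["t_min"], b["delta_c"]) for b in bins]
est = tk.permeability_from_lambda_slope(
    [f.lam for f in fits], [b["mean_diameter"] for b in bins])
print(f"P = {est.permeability:.2e} m/s, lambda0 = {est.lambda0:.0f} min")

# --- rotor viscometry ----------------------------------------------------
cal = flim.forster_hoffmann_calibrate([(0.52, 6.0), (1.28, 55.0)])
tau = flim.amplitude_weighted_lifetime([(0.55, 6.1), (1.95, 1.0)])
print(f"<tau> = {tau:.2f} ns -> eta_loc = {flim.viscosity_from_lifetime(tau, cal):.0f} mPa s")
```

prints

```
2253 966
92378
P = 1.02e-10 m/s, lambda0 = 53 min
<tau> = 0.75 ns -> eta_loc = 15 mPa s
```

2253 and 966 are the surfactant chains saturating the two interfaces of
the short- and long-headgroup systems (92378 beads in total); the
recovered permeability of ~1e-10 m/s matches the generating value (the
fitted 53 min offset is the scenario's 50 min lambda_0) and is
nine orders of magnitude below the diffusion-limited prediction
K D_m / l -- the signature of interface-limited transport; and the
0.75 ns amplitude-weighted lifetime of the dye at the long-headgroup
interface corresponds to a local viscosity of 15 mPa s.

A command-line interface mirrors the library:
`emultrans build|simulate|analyze|fit-kinetics|fit-flim|synth --help`.

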