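"""Synthetic data generators for every stage of the transport pipeline.

Three kinds of inputs are generated with the statistical structure the
analyses assume:

* droplet-level concentration time series with exponential uptake dynamics
  whose time scale grows linearly with droplet size (permeability-limited
  exchange), plus the slower two-timescale droplet-to-droplet exchange;
* TCSPC decay histograms as Poisson photon counts over an IRF-convolved
  multiexponential expectation;
* down-scaled bead-spring slab systems that preserve the production number
  density and surfactant concentration.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cg_system import (
    HS, HD, O, T, W,
    Configuration,
    InvalidParameterError,
    SystemComposition,
    TOPOLOGIES,
    surfactant_topology,
)
from .flim import (
    DEFAULT_IRF_FWHM_NS, DEFAULT_IRF_T0_NS, DEFAULT_WINDOW_NS,
    DecayHistogram, model_decay,
)
from .transport_kinetics import METERS_PER_MICRON, SECONDS_PER_MINUTE

__all__ = [
    "EmulsionScenario", "generate_droplet_records",
    "generate_delta_C_series", "generate_decay_histogram",
    "generate_md_fixture", "REFERENCE_COMPOSITION",
]

#: production-scale reference: 36x36x108 sigma box, rho=0.66, 2253/966 chains
REFERENCE_COMPOSITION = dict(box=(36.0, 36.0, 108.0), density=0.66, n_dye=100)
_REF_SURFACTANT_BEAD_CONC = 3 * 2253 / (36.0 * 36.0 * 108.0)  # = c_s


@dataclass
class EmulsionScenario:
    """Parameters of a synthetic emulsion uptake/exchange experiment.

    Droplet sizes are lognormal; the per-droplet uptake time scale follows
    permeability kinetics, lambda(d) = lambda0 + d/(6 P).  Defaults emulate
    an emulsion whose four size-class quartiles average about 5, 7, 9 and
    11 um, with the permeability (1e-10 m/s) and two-timescale constants
    (uptake ~200 min, exchange ~5400 min) observed for 1% anionic-surfactant
    emulsions.  Concentration noise is multiplicative Gaussian, matching
    intensity-derived measurements.
    """

    n_droplets: int = 200
    size_median_um: float = 7.8
    size_shape: float = 0.32
    permeability_m_s: float = 1e-10
    lambda0_min: float = 50.0
    eq3_lambda1_min: float = 200.0
    eq3_lambda2_min: float = 5400.0
    eq3_amplitude: float = 1.0
    delta_c0: float = 1.0
    delta_c_inf: float = 0.0
    noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_droplets", "size_median_um", "size_shape",
                     "permeability_m_s", "eq3_lambda1_min", "eq3_lambda2_min"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.noise < 0 or self.lambda0_min < 0:
            raise InvalidParameterError("noise and lambda0 must be >= 0")

    def lambda_of_diameter(self, d_um: np.ndarray) -> np.ndarray:
        """Uptake time scale (min) for droplets of diameter d (um)."""
        slope_s_per_m = 1.0 / (6.0 * self.permeability_m_s)
        slope_min_per_um = slope_s_per_m * METERS_PER_MICRON / SECONDS_PER_MINUTE
        return self.lambda0_min + slope_min_per_um * np.asarray(d_um)


def generate_droplet_records(
    scenario: EmulsionScenario, times_min: np.ndarray
) -> pd.DataFrame:
    """Droplet concentration table with exponentially relaxing dc = c_w - c_o.

    Each droplet gets a lognormal diameter and its permeability-limited time
    scale; the water and oil concentrations relax toward equilibrium with
    multiplicative Gaussian noise.  Columns match the droplet-record schema
    (droplet_id, t_min, d_um, c_oil, c_water).
    """
    rng = np.random.default_rng(scenario.seed)
    times = np.asarray(times_min, dtype=float)
    d = scenario.size_median_um * np.exp(
        rng.normal(0.0, scenario.size_shape, scenario.n_droplets))
    lam = scenario.lambda_of_diameter(d)
    rows = []
    c_eq = 0.5 * (scenario.delta_c0 + scenario.delta_c_inf)
    for i in range(scenario.n_droplets):
        decay = np.exp(-(times - times[0]) / lam[i])
        dc = scenario.delta_c_inf + (scenario.delta_c0 - scenario.delta_c_inf) * decay
        c_oil = c_eq * (1.0 - decay)
        c_water = c_oil + dc
        if scenario.noise > 0:
            c_oil = np.clip(
                c_oil * (1 + rng.normal(0, scenario.noise, len(times))), 0, None)
            c_water = np.clip(
                c_water * (1 + rng.normal(0, scenario.noise, len(times))), 0, None)
        for j, t in enumerate(times):
            rows.append((i, t, d[i], c_oil[j], c_water[j]))
    return pd.DataFrame(
        rows, columns=["droplet_id", "t_min", "d_um", "c_oil", "c_water"])


def generate_delta_C_series(
    scenario: EmulsionScenario, times_min: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Droplet-to-droplet concentration difference following the
    two-timescale model, with multiplicative noise."""
    rng = np.random.default_rng(scenario.seed + 1)
    t = np.asarray(times_min, dtype=float)
    y = scenario.eq3_amplitude * (
        np.exp(-t / scenario.eq3_lambda2_min)
        - np.exp(-t / scenario.eq3_lambda1_min))
    if scenario.noise > 0:
        y = y * (1 + rng.normal(0, scenario.noise, len(t)))
    return t, y


def generate_decay_histogram(
    components: list[tuple[float, float]],
    irf_fwhm: float = DEFAULT_IRF_FWHM_NS,
    total_photons: int = 100_000,
    seed: int = 0,
    n_bins: int = 500,
    window_ns: float = DEFAULT_WINDOW_NS,
    irf_t0: float = DEFAULT_IRF_T0_NS,
) -> DecayHistogram:
    """Poisson-sampled TCSPC histogram for a multiexponential decay.

    The expectation is the IRF-reconvolved periodic decay model scaled to
    ``total_photons``; per-bin counts are independent Poisson draws, so the
    realized total is itself Poisson-distributed around ``total_photons``.
    """
    if total_photons < 1:
        raise InvalidParameterError("need at least one photon")
    rng = np.random.default_rng(seed)
    dt = window_ns / n_bins
    bin_times = (np.arange(n_bins) + 0.5) * dt
    expected = model_decay(components, bin_times, float(total_photons),
                           irf_fwhm=irf_fwhm, irf_t0=irf_t0)
    counts = rng.poisson(expected)
    return DecayHistogram(bin_times, counts, irf=None, irf_fwhm=irf_fwhm,
                          irf_t0=irf_t0)


# ---------------------------------------------------------------------------
# scaled MD fixtures
# ---------------------------------------------------------------------------

def generate_md_fixture(
    scale_factor: float,
    surfactant_kind: str = "short",
    seed: int = 0,
    n_dye: int | None = None,
    prepared_interface: bool = False,
    build: bool = True,
) -> tuple[SystemComposition, Configuration | None]:
    """Down-scaled slab system preserving density and surfactant concentration.

    The production box (36 x 36 x 108 sigma) is scaled isotropically (the
    slab aspect L_z = 3 L_x is kept); the overall density 0.66 sigma^-3 and
    surfactant bead concentration c_s = 0.048 sigma^-3 are preserved, so all
    counts scale with the volume.  The dye count scales the same way unless
    ``n_dye`` overrides it (tiny fixtures would otherwise carry almost no
    dye).  With ``prepared_interface`` the configuration starts from
    surfactant-decorated interfaces and dye dispersed in the water slab
    instead of a fully random demixed state, shortening equilibration.
    """
    if not 0 < scale_factor <= 1:
        raise InvalidParameterError("scale_factor must be in (0, 1]")
    lx = 36.0 * scale_factor
    if lx < 6.0:
        raise InvalidParameterError(
            f"box {lx:.2f} sigma too small (< 6 sigma; below twice the "
            "interaction range)")
    box = (lx, lx, 3.0 * lx)
    volume = box[0] * box[1] * box[2]
    ns = surfactant_topology(surfactant_kind).n_s
    n_surf = round(_REF_SURFACTANT_BEAD_CONC * volume / ns)
    if n_dye is None:
        n_dye = round(100 * scale_factor**3)
    comp = SystemComposition(
        box=box, density=0.66, surfactant_kind=surfactant_kind,
        n_surfactant=n_surf, n_dye=n_dye)
    if not build:
        return comp, None
    if prepared_interface:
        config = _build_prepared_interface(comp, seed)
    else:
        from .cg_system import build_initial_configuration
        config = build_initial_configuration(comp, seed)
    return comp, config


def _build_prepared_interface(
    comp: SystemComposition, seed: int,
    min_distance: float = 0.9, bond_length: float = 0.97,
) -> Configuration:
    """Configuration with surfactant pre-adsorbed at both interfaces.

    Oil fills z < L_z/2; surfactant chains stand at z = L_z/2 and z = 0
    (periodic) with headgroups on the water side and tails toward the oil;
    dye molecules are dispersed in the bulk water slab.  Liquid beads are
    then inserted around these solutes by random sequential addition.
    """
    from ._kernels import insert_molecules

    rng = np.random.default_rng(seed)
    box = np.asarray(comp.box, dtype=float)
    lz = box[2]
    surf = surfactant_topology(comp.surfactant_kind)
    dye = TOPOLOGIES["dye"]
    counts = comp.bead_counts()

    placed: list[np.ndarray] = []
    species: list[int] = []
    molecule_id: list[int] = []
    bonds: list[tuple[int, int]] = []
    d2min = min_distance**2

    def clear(p):
        for q in placed:
            dvec = p - q
            dvec -= box * np.round(dvec / box)
            if dvec @ dvec < d2min:
                return False
        return True

    mol = 0
    idx = 0
    # surfactants split between the two interfaces
    for i in range(comp.n_surfactant):
        at_mid = i % 2 == 0
        iface = lz / 2.0 if at_mid else lz  # z=0 == z=lz
        direction = -1.0 if at_mid else +1.0  # tails point into the oil
        for attempt in range(5000):
            x0, y0 = rng.uniform(0, box[0]), rng.uniform(0, box[1])
            z0 = iface + (-direction) * rng.uniform(0.2, 0.8)
            tilt = rng.normal(0.0, 0.2, 2)
            step = np.array([tilt[0], tilt[1], direction])
            step *= bond_length / np.linalg.norm(step)
            chain = []
            ok = True
            for k in range(surf.n_s):
                p = np.array([
                    (x0 + step[0] * k) % box[0], (y0 + step[1] * k) % box[1],
                    (z0 + step[2] * k) % lz,
                ])
                if not clear(p):
                    ok = False
                    break
                chain.append(p)
            if ok:
                break
        else:
            raise InvalidParameterError(
                "could not place surfactants at the interface (box too small "
                "for the requested coverage)")
        first = idx
        for k, p in enumerate(chain):
            placed.append(p)
            species.append(surf.bead_sequence[k])
            molecule_id.append(mol)
            idx += 1
        bonds += [(first + a, first + b) for a, b in surf.bonds]
        mol += 1

    # dye starts in contact with the interfaces (experimentally it arrives
    # micelle-borne at the droplet surface); an in-contact start removes the
    # blob-diffusion lag so production probes the crossing step itself
    zlo, zhi = lz / 2.0 + 1.2, lz - 1.2
    for i_dye in range(comp.n_dye):
        near_mid = i_dye % 2 == 0
        chain: list[np.ndarray] = []
        for attempt in range(5000):
            if near_mid:
                z0 = lz / 2.0 + rng.uniform(1.5, 2.5)
            else:
                z0 = lz - rng.uniform(1.5, 2.5)
            z0 = float(np.clip(z0, zlo + 0.3, zhi - 0.3))
            p0 = np.array([
                rng.uniform(0, box[0]), rng.uniform(0, box[1]), z0,
            ])
            if not clear(p0):
                continue
            chain = [p0]
            while len(chain) < dye.n_s:
                for _try in range(50):
                    v = rng.normal(size=3)
                    v /= np.linalg.norm(v)
                    p = chain[-1] + bond_length * v
                    p[:2] %= box[:2]
                    self_ok = all(
                        np.sum((p - q) ** 2) >= d2min for q in chain[:-1])
                    if zlo <= p[2] < zhi and self_ok and clear(p):
                        chain.append(p)
                        break
                else:
                    chain = []
                    break
            if len(chain) == dye.n_s:
                break
        else:
            raise InvalidParameterError("could not place dye in the water slab")
        first = idx
        for k, p in enumerate(chain):
            placed.append(p)
            species.append(dye.bead_sequence[k])
            molecule_id.append(mol)
            idx += 1
        bonds += [(first + a, first + b) for a, b in dye.bonds]
        mol += 1

    fixed = np.array(placed) if placed else np.empty((0, 3))
    n_oil, n_water = counts["oil"], counts["water"]
    mol_sizes = np.ones(n_oil + n_water, dtype=np.int64)
    mol_lower = np.zeros(n_oil + n_water, dtype=bool)
    mol_lower[:n_oil] = True
    positions, err = insert_molecules(
        mol_sizes, mol_lower, box, lz / 2.0, min_distance, bond_length,
        100_000, int(seed) % (2**31), fixed)
    if err:
        raise InvalidParameterError(
            "random insertion of liquids failed around the prepared solutes")

    n_solute = len(fixed)
    all_species = np.concatenate([
        np.array(species, dtype=np.int8),
        np.full(n_oil, O, dtype=np.int8),
        np.full(n_water, W, dtype=np.int8),
    ])
    all_mol = np.concatenate([
        np.array(molecule_id, dtype=np.int64),
        mol + np.arange(n_oil + n_water, dtype=np.int64),
    ])
    velocities = rng.normal(0.0, 1.0, size=(len(all_species), 3))
    velocities -= velocities.mean(axis=0)
    return Configuration(
        positions, velocities, all_species,
        np.array(bonds, dtype=np.int64).reshape(-1, 2), all_mol, box,
    )
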