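"""Coarse-grained model definition for surfactant-decorated oil-water systems.

The model is a generic bead-spring representation of an oil/water/surfactant/dye
mixture in reduced Lennard-Jones units: every bead has unit mass ``m`` and unit
diameter ``sigma``, and the thermal energy sets the unit ``epsilon = kB*T``.
Five bead species exist:

====== =======================================================
label  meaning
====== =======================================================
W      water bead (five water molecules, volume 0.15 nm^3)
O      oil bead
Hs     hydrophilic surfactant headgroup bead
Hd     dye headgroup bead (soluble in both solvents)
T      hydrophobic tail bead (shared by dye and surfactants)
====== =======================================================

Two surfactant architectures are supported: a *short* three-bead chain
(one headgroup bead, ``Hs-T-T``), and a *long* seven-bead chain with a
five-bead headgroup (``Hs``x5 + ``T-T``) mimicking a surfactant with a
poly(ethylene oxide) headgroup.  The dye is always ``Hd-T-T``.

This module owns the species/topology/interaction bookkeeping, the
composition arithmetic (how many chains saturate the two liquid-liquid
interfaces of a periodic slab box), random initial-configuration building,
and the four-stage equilibration schedule.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "SPECIES",
    "W", "O", "HS", "HD", "T",
    "InteractionMatrix",
    "MoleculeTopology",
    "SystemComposition",
    "Configuration",
    "Stage",
    "length_unit_nm",
    "surfactant_count",
    "default_interaction_matrix",
    "build_initial_configuration",
    "equilibration_schedule",
    "write_xyz", "read_xyz", "write_bonds", "read_bonds",
]

#: canonical species ordering; integer codes index the interaction tables
SPECIES: tuple[str, ...] = ("W", "O", "Hs", "Hd", "T")
W, O, HS, HD, T = range(5)
_SPECIES_INDEX = {label: i for i, label in enumerate(SPECIES)}

#: LJ cutoff in units of sigma
LJ_CUTOFF = 3.0
#: WCA cutoff: the LJ minimum
WCA_CUTOFF = 2.0 ** (1.0 / 6.0)


class InvalidParameterError(ValueError):
    """A model parameter is outside its physical domain."""


class PackingError(RuntimeError):
    """Random insertion failed to place a bead without overlap."""


def species_index(label: str | int) -> int:
    if isinstance(label, (int, np.integer)):
        if not 0 <= int(label) < len(SPECIES):
            raise InvalidParameterError(f"unknown species code {label}")
        return int(label)
    try:
        return _SPECIES_INDEX[label]
    except KeyError:
        raise InvalidParameterError(f"unknown species label {label!r}") from None


# ---------------------------------------------------------------------------
# interaction matrix
# ---------------------------------------------------------------------------

@dataclass
class InteractionMatrix:
    """Symmetric species-pair table of nonbonded interaction parameters.

    ``epsilon[i, j]`` is the pair interaction strength in units of the
    thermal energy; ``wca[i, j]`` selects the purely repulsive
    Weeks-Chandler-Andersen form (LJ truncated at its minimum ``2^(1/6)
    sigma`` and shifted up by epsilon) instead of the attractive LJ form
    truncated at ``cutoff_lj`` (energy-shifted to vanish at the cutoff).
    """

    epsilon: np.ndarray
    wca: np.ndarray
    cutoff_lj: float = LJ_CUTOFF

    def __post_init__(self) -> None:
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        self.wca = np.asarray(self.wca, dtype=bool)
        n = len(SPECIES)
        if self.epsilon.shape != (n, n) or self.wca.shape != (n, n):
            raise InvalidParameterError("interaction tables must be 5x5")
        if not np.allclose(self.epsilon, self.epsilon.T):
            raise InvalidParameterError("epsilon table must be symmetric")
        if not np.array_equal(self.wca, self.wca.T):
            raise InvalidParameterError("mode table must be symmetric")
        if np.any(self.epsilon <= 0):
            raise InvalidParameterError("all epsilon entries must be positive")

    def entry(self, a: str | int, b: str | int) -> tuple[float, str]:
        """Return ``(epsilon, mode)`` for a species pair; mode is 'LJ' or 'WCA'."""
        i, j = species_index(a), species_index(b)
        return float(self.epsilon[i, j]), ("WCA" if self.wca[i, j] else "LJ")

    def with_overrides(
        self, overrides: Iterable[tuple[str | int, str | int, float | None, str]]
    ) -> "InteractionMatrix":
        """New matrix with ``(a, b, epsilon, mode)`` entries replaced.

        ``epsilon=None`` keeps the current strength; mode is 'LJ' or 'WCA'.
        """
        eps = self.epsilon.copy()
        wca = self.wca.copy()
        for a, b, e, mode in overrides:
            i, j = species_index(a), species_index(b)
            if e is not None:
                if e <= 0:
                    raise InvalidParameterError("epsilon override must be positive")
                eps[i, j] = eps[j, i] = e
            if mode not in ("LJ", "WCA"):
                raise InvalidParameterError(f"unknown mode {mode!r}")
            wca[i, j] = wca[j, i] = mode == "WCA"
        return InteractionMatrix(eps, wca, self.cutoff_lj)

    def tables(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-pair ``(epsilon, rcut^2, energy shift)`` tables for the engine.

        The shift makes the pair energy continuous at its cutoff:
        ``+epsilon`` for WCA, ``-U_LJ(r_cut)`` for truncated-shifted LJ.
        """
        eps = self.epsilon
        rc = np.where(self.wca, WCA_CUTOFF, self.cutoff_lj)
        inv6 = rc ** -6.0
        shift = np.where(self.wca, eps, -4.0 * eps * (inv6 * inv6 - inv6))
        return eps.copy(), (rc * rc), shift


def default_interaction_matrix(surfactant_kind: str = "short") -> InteractionMatrix:
    """The model's nonbonded interaction table.

    Same-species pairs interact with strength 1 (the thermal energy); the
    water-oil pair is purely repulsive (WCA), making the two liquids
    immiscible.  The surfactant headgroup entries depend on the chain
    architecture: ``Hs-W`` is 1.9 (short) or 1.1 (long), chosen to give the
    two kinds a similar interfacial coverage, and ``Hs-Hd`` is 3.6 (short) or
    0.225 (long), encoding the relative hydrophilic strength of the headgroups.
    """
    if surfactant_kind not in ("short", "long"):
        raise InvalidParameterError(f"unknown surfactant kind {surfactant_kind!r}")
    short = surfactant_kind == "short"
    eps = np.ones((5, 5))
    wca = np.zeros((5, 5), dtype=bool)

    def set_pair(a, b, e=None, mode="LJ"):
        i, j = species_index(a), species_index(b)
        if e is not None:
            eps[i, j] = eps[j, i] = e
        wca[i, j] = wca[j, i] = mode == "WCA"

    set_pair("W", "O", 1.0, "WCA")
    set_pair("Hs", "W", 1.9 if short else 1.1)
    set_pair("Hs", "O", 0.2)
    set_pair("Hs", "Hd", 3.6 if short else 0.225)
    set_pair("Hs", "T", 0.2)
    set_pair("Hd", "W", 0.9)
    set_pair("Hd", "O", 0.9)
    set_pair("Hd", "T", 0.9)
    set_pair("T", "W", 0.2)
    set_pair("T", "O", 0.9)
    return InteractionMatrix(eps, wca)


# ---------------------------------------------------------------------------
# molecule topologies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MoleculeTopology:
    """Bead sequence and bond list of one molecule type."""

    name: str
    bead_sequence: tuple[int, ...]
    bonds: tuple[tuple[int, int], ...]

    @property
    def n_s(self) -> int:
        """Number of beads per chain."""
        return len(self.bead_sequence)


def _chain(name: str, seq: Sequence[int]) -> MoleculeTopology:
    bonds = tuple((i, i + 1) for i in range(len(seq) - 1))
    return MoleculeTopology(name, tuple(seq), bonds)


TOPOLOGIES: dict[str, MoleculeTopology] = {
    "water": MoleculeTopology("water", (W,), ()),
    "oil": MoleculeTopology("oil", (O,), ()),
    "dye": _chain("dye", (HD, T, T)),
    "surfactant_short": _chain("surfactant_short", (HS, T, T)),
    "surfactant_long": _chain("surfactant_long", (HS, HS, HS, HS, HS, T, T)),
}


def surfactant_topology(kind: str) -> MoleculeTopology:
    if kind not in ("short", "long"):
        raise InvalidParameterError(f"unknown surfactant kind {kind!r}")
    return TOPOLOGIES[f"surfactant_{kind}"]


# ---------------------------------------------------------------------------
# composition arithmetic
# ---------------------------------------------------------------------------

def length_unit_nm(bead_volume_nm3: float = 0.15) -> float:
    """Physical size of one reduced length unit sigma, in nm.

    One water bead lumps five water molecules of total volume ``v_w``; sigma
    maps onto the diameter of a sphere of that volume, ``(6 v_w / pi)^(1/3)``.
    """
    if bead_volume_nm3 <= 0:
        raise InvalidParameterError("bead volume must be positive")
    return (6.0 * bead_volume_nm3 / math.pi) ** (1.0 / 3.0)


def surfactant_count(
    box_xy: tuple[float, float],
    area_per_surfactant_nm2: float = 0.5,
    bead_volume_nm3: float = 0.15,
    surfactant_kind: str = "short",
) -> int:
    """Number of surfactant chains that saturate both interfaces of the slab.

    The periodic slab box has two liquid-liquid interfaces of area
    ``L_x * L_y`` each, so ``N_s = 2 L_x L_y l_u^2 / A_s`` with ``l_u`` the
    nm-per-sigma mapping and ``A_s`` the experimental area per adsorbed
    surfactant.  For the long (seven-bead) chain the count is rescaled to
    preserve the total surfactant bead concentration
    ``c_s = n_s N_s / V_box`` of the short system.
    """
    lx, ly = box_xy[0], box_xy[1]
    if lx <= 0 or ly <= 0:
        raise InvalidParameterError("box lengths must be positive")
    if area_per_surfactant_nm2 <= 0:
        raise InvalidParameterError("area per surfactant must be positive")
    lu = length_unit_nm(bead_volume_nm3)
    n_short = round(2.0 * lx * ly * lu * lu / area_per_surfactant_nm2)
    if surfactant_kind == "short":
        return n_short
    if surfactant_kind == "long":
        ns_short = TOPOLOGIES["surfactant_short"].n_s
        ns_long = TOPOLOGIES["surfactant_long"].n_s
        return round(ns_short * n_short / ns_long)
    raise InvalidParameterError(f"unknown surfactant kind {surfactant_kind!r}")


@dataclass
class SystemComposition:
    """Box geometry and species counts of one simulated system.

    Defaults reproduce the production setup: a 36 x 36 x 108 sigma slab box at
    overall number density 0.66 sigma^-3, interfaces saturated with surfactant
    (0.5 nm^2 per molecule), 100 dye molecules, and a 50:50 oil/water split.
    """

    box: tuple[float, float, float] = (36.0, 36.0, 108.0)
    density: float = 0.66
    surfactant_kind: str = "short"
    n_surfactant: int | None = None
    n_dye: int = 100
    solvent_split: float = 0.5
    bead_volume_nm3: float = 0.15
    area_per_surfactant_nm2: float = 0.5

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.box):
            raise InvalidParameterError("box lengths must be positive")
        if self.density <= 0:
            raise InvalidParameterError("density must be positive")
        if not 0.0 <= self.solvent_split <= 1.0:
            raise InvalidParameterError("solvent split must lie in [0, 1]")
        if self.n_dye < 0:
            raise InvalidParameterError("dye count must be non-negative")
        if self.surfactant_kind not in ("short", "long"):
            raise InvalidParameterError(
                f"unknown surfactant kind {self.surfactant_kind!r}")
        if self.n_surfactant is None:
            self.n_surfactant = surfactant_count(
                self.box[:2], self.area_per_surfactant_nm2,
                self.bead_volume_nm3, self.surfactant_kind)

    @property
    def volume(self) -> float:
        return self.box[0] * self.box[1] * self.box[2]

    @property
    def total_beads(self) -> int:
        """Total bead count, ``floor(rho * V)``."""
        return int(self.density * self.volume)

    @property
    def surfactant_concentration(self) -> float:
        """Surfactant bead concentration ``c_s = n_s N_s / V`` in sigma^-3."""
        ns = surfactant_topology(self.surfactant_kind).n_s
        return ns * self.n_surfactant / self.volume

    def bead_counts(self) -> dict[str, int]:
        """Beads per molecule class; liquids fill up to ``total_beads``."""
        ns = surfactant_topology(self.surfactant_kind).n_s
        surf = ns * self.n_surfactant
        dye = 3 * self.n_dye
        liquid = self.total_beads - surf - dye
        if liquid < 0:
            raise InvalidParameterError("solute beads exceed the total bead count")
        oil = round(liquid * (1.0 - self.solvent_split))
        return {"surfactant": surf, "dye": dye, "oil": oil, "water": liquid - oil}

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"composition": self.to_dict()}, fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "SystemComposition":
        with open(path) as fh:
            data = yaml.safe_load(fh)["composition"]
        data["box"] = tuple(data["box"])
        return cls(**data)


# ---------------------------------------------------------------------------
# configuration container
# ---------------------------------------------------------------------------

@dataclass
class Configuration:
    """Full particle state of a simulation.

    positions/velocities in reduced units, species codes per bead, adjacent-
    pair bond list (global bead indices), per-bead molecule id, and periodic
    box lengths.
    """

    positions: np.ndarray
    velocities: np.ndarray
    species: np.ndarray
    bonds: np.ndarray
    molecule_id: np.ndarray
    box: np.ndarray
    time_step_index: int = 0

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=float)
        self.species = np.ascontiguousarray(self.species, dtype=np.int8)
        self.bonds = np.ascontiguousarray(
            self.bonds if len(self.bonds) else np.empty((0, 2)), dtype=np.int64
        ).reshape(-1, 2)
        self.molecule_id = np.ascontiguousarray(self.molecule_id, dtype=np.int64)
        self.box = np.asarray(self.box, dtype=float)
        n = len(self.positions)
        if self.velocities.shape != (n, 3) or self.positions.shape != (n, 3):
            raise InvalidParameterError("positions/velocities must be (N, 3)")
        if len(self.species) != n or len(self.molecule_id) != n:
            raise InvalidParameterError("species/molecule_id length mismatch")
        if not np.all(np.isfinite(self.positions)) or not np.all(
            np.isfinite(self.velocities)
        ):
            raise InvalidParameterError("non-finite coordinates")
        if len(self.bonds) and (
            self.bonds.min() < 0 or self.bonds.max() >= n
        ):
            raise InvalidParameterError("bond index out of range")
        if len(self.bonds) and np.any(
            self.molecule_id[self.bonds[:, 0]] != self.molecule_id[self.bonds[:, 1]]
        ):
            raise InvalidParameterError("bond partners must share a molecule")

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def copy(self) -> "Configuration":
        return Configuration(
            self.positions.copy(), self.velocities.copy(), self.species.copy(),
            self.bonds.copy(), self.molecule_id.copy(), self.box.copy(),
            self.time_step_index,
        )

    def wrap(self) -> None:
        """Wrap positions into the primary box in place."""
        self.positions -= np.floor(self.positions / self.box) * self.box

    def kinetic_temperature(self) -> float:
        """Instantaneous kinetic temperature with three COM dof removed."""
        n = self.n_beads
        dof = max(3 * n - 3, 1)
        return float(np.sum(self.velocities**2) / dof)


# ---------------------------------------------------------------------------
# initial configuration builder
# ---------------------------------------------------------------------------

def _molecule_list(composition: SystemComposition) -> list[MoleculeTopology]:
    counts = composition.bead_counts()
    mols: list[MoleculeTopology] = []
    mols += [TOPOLOGIES["oil"]] * counts["oil"]
    mols += [surfactant_topology(composition.surfactant_kind)] * composition.n_surfactant
    mols += [TOPOLOGIES["dye"]] * composition.n_dye
    mols += [TOPOLOGIES["water"]] * counts["water"]
    return mols


def build_initial_configuration(
    composition: SystemComposition,
    seed: int,
    min_distance: float = 0.9,
    bond_length: float = 0.97,
    max_retries: int = 100_000,
) -> Configuration:
    """Random demixed starting state: oil in the lower half-slab, the rest above.

    Beads are inserted by random sequential addition with a hard minimum
    distance; chain molecules grow bead by bead at near-equilibrium bond
    length.  Velocities are Maxwell-Boltzmann at T=1 with the net momentum
    removed.  Deterministic for a given seed.
    """
    from ._kernels import insert_molecules  # deferred: numba compile cost

    box = np.asarray(composition.box, dtype=float)
    rng = np.random.default_rng(seed)
    mols = _molecule_list(composition)
    n_total = sum(m.n_s for m in mols)

    mol_sizes = np.array([m.n_s for m in mols], dtype=np.int64)
    mol_lower = np.array([m.name == "oil" for m in mols])
    positions, err = insert_molecules(
        mol_sizes, mol_lower, box, box[2] / 2.0, min_distance, bond_length,
        int(max_retries), int(seed) % (2**31), np.empty((0, 3)),
    )
    if err:
        raise PackingError(
            f"density too high: random insertion failed after {max_retries} "
            "retries for one bead")

    species = np.empty(n_total, dtype=np.int8)
    molecule_id = np.empty(n_total, dtype=np.int64)
    bonds: list[tuple[int, int]] = []
    idx = 0
    for mol_id, topo in enumerate(mols):
        species[idx:idx + topo.n_s] = topo.bead_sequence
        molecule_id[idx:idx + topo.n_s] = mol_id
        bonds += [(idx + a, idx + b) for a, b in topo.bonds]
        idx += topo.n_s

    velocities = rng.normal(0.0, 1.0, size=(n_total, 3))
    velocities -= velocities.mean(axis=0)
    return Configuration(
        positions, velocities, species, np.array(bonds, dtype=np.int64),
        molecule_id, box,
    )


# ---------------------------------------------------------------------------
# equilibration schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Stage:
    """One leg of the equilibration/production protocol.

    ``interaction_overrides`` are ``(species_a, species_b, epsilon, mode)``
    entries applied on top of the default matrix for the duration of the
    stage; ``frozen_species`` are bead species whose positions are not
    integrated.
    """

    name: str
    n_steps: int
    interaction_overrides: tuple = ()
    frozen_species: frozenset = frozenset()


def equilibration_schedule(
    surfactant_kind: str = "short", steps_scale: float = 1.0
) -> list[Stage]:
    """The four-stage protocol leading into production.

    1. demix the liquids with all solutes frozen (1e6 steps);
    2. homogenize the surfactant by setting every T/Hs-liquid strength to
       the thermal energy (1e7 steps);
    3. form the surfactant-decorated interface with the full interaction
       table, but keep the dye in the aqueous phase by making Hd-O and T-O
       purely repulsive (3.5e7 steps);
    4. production with the full table (2e8 steps).

    ``steps_scale`` scales every stage length (down-scaled systems decorrelate
    proportionally faster); counts are kept at least 1.
    """
    if surfactant_kind not in ("short", "long"):
        raise InvalidParameterError(f"unknown surfactant kind {surfactant_kind!r}")
    if steps_scale <= 0:
        raise InvalidParameterError("steps_scale must be positive")

    def steps(n: float) -> int:
        return max(1, int(round(n * steps_scale)))

    mix = tuple(
        (a, b, 1.0, "LJ") for a in ("T", "Hs") for b in ("W", "O")
    )
    dye_out_of_oil = (("Hd", "O", None, "WCA"), ("T", "O", None, "WCA"))
    return [
        Stage("demix_liquids", steps(1e6),
              frozen_species=frozenset({HS, HD, T})),
        Stage("homogenize_surfactant", steps(1e7), interaction_overrides=mix),
        Stage("form_interface", steps(3.5e7),
              interaction_overrides=dye_out_of_oil),
        Stage("production", steps(2e8)),
    ]


# ---------------------------------------------------------------------------
# extended-XYZ + bond-table I/O
# ---------------------------------------------------------------------------

def write_xyz(config: Configuration, path, mode: str = "w") -> None:
    """Append one extended-XYZ frame (species, position, velocity, molecule id)."""
    b = config.box
    with open(path, mode) as fh:
        fh.write(f"{config.n_beads}\n")
        fh.write(
            f'Lattice="{b[0]} 0 0 0 {b[1]} 0 0 0 {b[2]}" '
            "Properties=species:S:1:pos:R:3:velo:R:3:molecule:I:1 "
            f"Time={config.time_step_index}\n"
        )
        for i in range(config.n_beads):
            x, y, z = config.positions[i]
            vx, vy, vz = config.velocities[i]
            fh.write(
                f"{SPECIES[config.species[i]]} {x:.8g} {y:.8g} {z:.8g} "
                f"{vx:.8g} {vy:.8g} {vz:.8g} {config.molecule_id[i]}\n"
            )


def read_xyz(path, bonds: np.ndarray | None = None) -> list[Configuration]:
    """Read every frame of an extended-XYZ file written by :func:`write_xyz`."""
    frames: list[Configuration] = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            comment = fh.readline()
            lattice = comment.split('"')[1].split()
            box = np.array([float(lattice[0]), float(lattice[4]), float(lattice[8])])
            step = 0
            for tok in comment.split():
                if tok.startswith("Time="):
                    step = int(float(tok[5:]))
            pos = np.empty((n, 3))
            vel = np.empty((n, 3))
            spec = np.empty(n, dtype=np.int8)
            mol = np.empty(n, dtype=np.int64)
            for i in range(n):
                parts = fh.readline().split()
                spec[i] = species_index(parts[0])
                pos[i] = [float(v) for v in parts[1:4]]
                vel[i] = [float(v) for v in parts[4:7]]
                mol[i] = int(parts[7])
            frames.append(Configuration(
                pos, vel, spec,
                bonds if bonds is not None else np.empty((0, 2), dtype=np.int64),
                mol, box, step,
            ))
    return frames


def write_bonds(config: Configuration, path) -> None:
    with open(path, "w") as fh:
        fh.write("molecule_id,bead_a,bead_b\n")
        for a, b in config.bonds:
            fh.write(f"{config.molecule_id[a]},{a},{b}\n")


def read_bonds(path) -> np.ndarray:
    data = np.loadtxt(path, delimiter=",", skiprows=1, dtype=np.int64, ndmin=2)
    if data.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    return data[:, 1:3]
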