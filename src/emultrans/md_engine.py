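"""Minimal NVT molecular-dynamics engine for the bead-spring emulsion model.

Reduced units throughout: lengths in sigma, energies in the thermal energy
epsilon, masses m=1, time in tau = sigma*sqrt(m/epsilon).  The equations of
motion are integrated with velocity Verlet (time step 0.005 tau by default)
coupled to a single Nose-Hoover thermostat; with the thermostat disabled the
step is plain NVE velocity Verlet.  Nonbonded interactions are truncated
12-6 LJ (energy-shifted at the cutoff, forces untouched) or WCA, per the
species-pair interaction matrix; bonds are Kremer-Grest FENE springs
(k = 30 epsilon/sigma^2, R0 = 1.5 sigma) combined with a unit-epsilon WCA
core, and bonded pairs are excluded from the nonbonded sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .cg_system import (
    Configuration,
    InteractionMatrix,
    InvalidParameterError,
    SystemComposition,
    Stage,
    build_initial_configuration,
    default_interaction_matrix,
    write_xyz,
)

__all__ = [
    "ThermostatState", "Trajectory",
    "lj_pair_energy", "lj_pair_force", "wca_pair_energy", "wca_pair_force",
    "fene_bond_energy", "fene_bond_force",
    "compute_forces", "nvt_step", "run_simulation",
    "SimulationError", "BondOverstretchError",
]

FENE_K = _kernels.FENE_K
FENE_R0 = _kernels.FENE_R0
DEFAULT_DT = 0.005


class SimulationError(RuntimeError):
    """The integration failed (non-finite coordinates or singular pair)."""


class BondOverstretchError(SimulationError):
    """A FENE bond reached its maximum extension R0."""


_ERRORS = {
    1: BondOverstretchError,
    2: SimulationError,
    3: SimulationError,
    4: SimulationError,
}
_ERROR_MSG = {
    1: "FENE bond overstretched (r >= R0)",
    2: "non-finite energy/coordinates (numerical blow-up)",
    3: "pair distance collapsed to zero (singularity)",
    4: "neighbor-list capacity exceeded",
}


def _raise_engine_error(code: int, step: int | None = None) -> None:
    if code:
        msg = _ERROR_MSG.get(code, "engine failure")
        if step is not None:
            msg += f" at step {step}"
        raise _ERRORS.get(code, SimulationError)(msg)


# ---------------------------------------------------------------------------
# pair/bond potentials (scalar reference forms)
# ---------------------------------------------------------------------------

def lj_pair_energy(r: float, epsilon: float, cutoff: float = 3.0,
                   shifted: bool = True) -> float:
    """12-6 Lennard-Jones pair energy, zero beyond the cutoff.

    With ``shifted`` (the engine's convention) the energy is offset so that it
    vanishes continuously at the cutoff; the force is untouched by the shift.
    """
    if r <= 0:
        raise InvalidParameterError("pair distance must be positive")
    if epsilon <= 0:
        raise InvalidParameterError("epsilon must be positive")
    if r > cutoff:
        return 0.0
    inv6 = r ** -6.0
    u = 4.0 * epsilon * (inv6 * inv6 - inv6)
    if shifted:
        c6 = cutoff ** -6.0
        u -= 4.0 * epsilon * (c6 * c6 - c6)
    return u


def lj_pair_force(r: float, epsilon: float, cutoff: float = 3.0) -> float:
    """Radial LJ force magnitude, positive = repulsive; zero beyond cutoff."""
    if r <= 0:
        raise InvalidParameterError("pair distance must be positive")
    if r > cutoff:
        return 0.0
    inv6 = r ** -6.0
    return 24.0 * epsilon * (2.0 * inv6 * inv6 - inv6) / r


def wca_pair_energy(r: float, epsilon: float) -> float:
    """Purely repulsive WCA energy: LJ cut at 2^(1/6) sigma, shifted by epsilon."""
    if r <= 0:
        raise InvalidParameterError("pair distance must be positive")
    if r > 2.0 ** (1.0 / 6.0):
        return 0.0
    inv6 = r ** -6.0
    return 4.0 * epsilon * (inv6 * inv6 - inv6) + epsilon


def wca_pair_force(r: float, epsilon: float) -> float:
    if r <= 0:
        raise InvalidParameterError("pair distance must be positive")
    if r > 2.0 ** (1.0 / 6.0):
        return 0.0
    inv6 = r ** -6.0
    return 24.0 * epsilon * (2.0 * inv6 * inv6 - inv6) / r


def fene_bond_energy(r: float, k: float = FENE_K, r0: float = FENE_R0,
                     epsilon: float = 1.0) -> float:
    """FENE spring energy plus the WCA core between the bonded pair.

    The combined potential has its minimum near 0.961 sigma for the
    Kremer-Grest defaults.  Raises at r >= R0 (finite extensibility).
    """
    if not 0 < r:
        raise InvalidParameterError("bond length must be positive")
    if r >= r0:
        raise BondOverstretchError(f"bond length {r} exceeds R0={r0}")
    u = -0.5 * k * r0 * r0 * math.log(1.0 - (r / r0) ** 2)
    return u + wca_pair_energy(r, epsilon)


def fene_bond_force(r: float, k: float = FENE_K, r0: float = FENE_R0,
                    epsilon: float = 1.0) -> float:
    """Radial force of the combined FENE+WCA bond (positive = repulsive)."""
    if r >= r0:
        raise BondOverstretchError(f"bond length {r} exceeds R0={r0}")
    f = -k * r / (1.0 - (r / r0) ** 2)
    return f + wca_pair_force(r, epsilon)


# ---------------------------------------------------------------------------
# forces on a configuration
# ---------------------------------------------------------------------------

def _bond_partner_table(n: int, bonds: np.ndarray) -> np.ndarray:
    bp = -np.ones((n, 2), dtype=np.int64)
    for a, b in bonds:
        for i, j in ((a, b), (b, a)):
            if bp[i, 0] < 0:
                bp[i, 0] = j
            elif bp[i, 1] < 0:
                bp[i, 1] = j
            else:
                raise InvalidParameterError(
                    "linear-chain topology expected (max 2 bonds per bead)")
    return bp


def _max_neighbors(density: float, rlist: float) -> int:
    est = density * (4.0 / 3.0) * math.pi * rlist**3
    return max(32, int(1.8 * est))


def compute_forces(
    config: Configuration, matrix: InteractionMatrix, skin: float = 0.3
) -> tuple[np.ndarray, float]:
    """Forces and total potential energy of a configuration.

    Pair terms are summed over a periodic cell/Verlet neighbor list; forces
    are the exact negative gradient of the reported potential energy.
    """
    pos = np.ascontiguousarray(config.positions % config.box)
    eps, rcut2, shift = matrix.tables()
    rlist = math.sqrt(rcut2.max()) + skin
    density = config.n_beads / float(np.prod(config.box))
    max_neigh = _max_neighbors(density, rlist)
    bp = _bond_partner_table(config.n_beads, config.bonds)
    forces = np.zeros((config.n_beads, 3))
    while True:
        neigh, counts, ok = _kernels.build_neighbor_list(
            pos, config.box, rlist, max_neigh)
        if ok:
            break
        max_neigh *= 2
    pe_p, err = _kernels.pair_forces(
        pos, config.species, config.box, eps, rcut2, shift, bp,
        neigh, counts, max_neigh, forces)
    _raise_engine_error(err)
    pe_b, err = _kernels.bond_forces(pos, config.box, config.bonds, forces)
    _raise_engine_error(err)
    return forces, pe_p + pe_b


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

@dataclass
class ThermostatState:
    """Nose-Hoover thermostat: target T, friction variable xi, coupling time.

    ``coupling_time=0`` disables the thermostat (plain NVE velocity Verlet).
    """

    target_temperature: float = 1.0
    friction_variable: float = 0.0
    coupling_time: float = 0.5

    def __post_init__(self) -> None:
        if self.coupling_time < 0:
            raise InvalidParameterError("coupling time must be >= 0")
        if self.target_temperature <= 0:
            raise InvalidParameterError("target temperature must be positive")


@dataclass
class Trajectory:
    """In-memory trajectory: static topology plus snapshot positions and a log."""

    species: np.ndarray
    molecule_id: np.ndarray
    bonds: np.ndarray
    box: np.ndarray
    snapshot_steps: np.ndarray
    positions: np.ndarray  # (n_snapshots, N, 3) float32
    log: pd.DataFrame
    final: Configuration
    surfactant_kind: str | None = None

    @property
    def n_snapshots(self) -> int:
        return len(self.snapshot_steps)

    def snapshot(self, i: int) -> Configuration:
        return Configuration(
            self.positions[i].astype(float), np.zeros_like(self.positions[i], dtype=float),
            self.species, self.bonds, self.molecule_id, self.box,
            int(self.snapshot_steps[i]),
        )

    def save(self, prefix: str) -> None:
        """Write snapshots as a multi-frame extended-XYZ file plus a CSV log."""
        path = f"{prefix}.xyz"
        for i in range(self.n_snapshots):
            write_xyz(self.snapshot(i), path, mode="w" if i == 0 else "a")
        self.log.to_csv(f"{prefix}_log.csv", index=False)


def _run_kernel(config: Configuration, matrix: InteractionMatrix,
                thermostat: ThermostatState | None, dt: float, n_steps: int,
                mobile: np.ndarray, skin: float,
                snap_every: int, log_every: int):
    eps, rcut2, shift = matrix.tables()
    bp = _bond_partner_table(config.n_beads, config.bonds)
    density = config.n_beads / float(np.prod(config.box))
    rlist = math.sqrt(rcut2.max()) + skin
    max_neigh = _max_neighbors(density, rlist)
    n_snap_cap = n_steps // snap_every + 1 if snap_every > 0 else 0
    n_log_cap = n_steps // log_every + 1 if log_every > 0 else 0
    snaps = np.empty((n_snap_cap, config.n_beads, 3), dtype=np.float32)
    snap_steps = np.empty(n_snap_cap, dtype=np.int64)
    log_rows = np.empty((n_log_cap, 5))
    if thermostat is None:
        tau_t, temp, xi = 0.0, 1.0, 0.0
    else:
        tau_t = thermostat.coupling_time
        temp = thermostat.target_temperature
        xi = thermostat.friction_variable
    config.wrap()
    while True:
        code, xi, n_snap, n_log, pe = _kernels.integrate(
            config.positions, config.velocities, config.species, mobile,
            config.box, eps, rcut2, shift, bp, config.bonds,
            dt, n_steps, config.time_step_index, temp, tau_t, xi, skin,
            max_neigh, snap_every, snaps, snap_steps, log_every, log_rows)
        if code == 4:
            max_neigh *= 2
            continue
        break
    _raise_engine_error(code, step=config.time_step_index)
    config.time_step_index += n_steps
    if thermostat is not None:
        thermostat.friction_variable = xi
    return snaps[:n_snap], snap_steps[:n_snap], log_rows[:n_log]


def nvt_step(
    config: Configuration,
    thermostat: ThermostatState | None,
    matrix: InteractionMatrix,
    dt: float = DEFAULT_DT,
    n_steps: int = 1,
    mobile_species: set[int] | None = None,
    skin: float = 0.3,
) -> Configuration:
    """Advance a configuration by ``n_steps`` velocity-Verlet steps in place.

    ``thermostat=None`` (or coupling_time 0) integrates NVE.
    """
    if dt <= 0:
        raise InvalidParameterError("time step must be positive")
    if mobile_species is None:
        mobile = np.ones(config.n_beads, dtype=bool)
    else:
        mobile = np.isin(config.species, list(mobile_species))
    _run_kernel(config, matrix, thermostat, dt, n_steps, mobile, skin, 0, 0)
    return config


def run_simulation(
    system: Configuration | SystemComposition,
    schedule: list[Stage],
    seed: int = 0,
    snapshot_interval: int = 100_000,
    matrix: InteractionMatrix | None = None,
    surfactant_kind: str | None = None,
    dt: float = DEFAULT_DT,
    thermostat: ThermostatState | None = None,
    log_interval: int | None = None,
    skin: float = 0.3,
    warmup_steps: int = 0,
    warmup_dt: float | None = None,
    verbose: bool = False,
) -> Trajectory:
    """Run a staged NVT simulation and collect snapshots and an energy log.

    ``system`` may be a composition (a fresh random configuration is built
    from ``seed``) or an existing configuration.  Each stage applies its
    interaction overrides on top of the default matrix and freezes the listed
    species; velocities carry over across stage boundaries.  Snapshots are
    taken every ``snapshot_interval`` steps (global step counter).

    ``warmup_steps`` runs an unlogged soft-start leg at the reduced time step
    ``warmup_dt`` (default dt/5) under the first stage's interactions before
    the schedule proper, relaxing the residual close contacts of randomly
    inserted configurations; it does not advance the global step counter.
    """
    if isinstance(system, SystemComposition):
        kind = system.surfactant_kind
        config = build_initial_configuration(system, seed)
    else:
        config = system
        kind = surfactant_kind or "short"
    base = matrix if matrix is not None else default_interaction_matrix(kind)
    thermo = thermostat if thermostat is not None else ThermostatState()
    if log_interval is None:
        log_interval = max(1, snapshot_interval // 10)

    all_snaps, all_steps, all_logs = [], [], []
    if warmup_steps > 0 and schedule:
        first = schedule[0]
        warm_matrix = base.with_overrides(first.interaction_overrides)
        mobile = ~np.isin(config.species, list(first.frozen_species)) \
            if first.frozen_species else np.ones(config.n_beads, dtype=bool)
        _run_kernel(config, warm_matrix, thermo,
                    warmup_dt if warmup_dt is not None else dt / 5.0,
                    warmup_steps, mobile, skin, 0, 0)
        config.time_step_index -= warmup_steps

    for stage in schedule:
        stage_matrix = base.with_overrides(stage.interaction_overrides)
        mobile = ~np.isin(config.species, list(stage.frozen_species)) \
            if stage.frozen_species else np.ones(config.n_beads, dtype=bool)
        snaps, steps, log_rows = _run_kernel(
            config, stage_matrix, thermo, dt, stage.n_steps, mobile, skin,
            snapshot_interval, log_interval)
        all_snaps.append(snaps)
        all_steps.append(steps)
        all_logs.append(log_rows)
        if verbose:
            t_now = log_rows[-1, 3] if len(log_rows) else float("nan")
            print(f"stage {stage.name}: {stage.n_steps} steps done, T={t_now:.3f}")

    log = pd.DataFrame(
        np.concatenate(all_logs) if all_logs else np.empty((0, 5)),
        columns=["step", "kinetic", "potential", "temperature", "xi"],
    )
    return Trajectory(
        species=config.species.copy(), molecule_id=config.molecule_id.copy(),
        bonds=config.bonds.copy(), box=config.box.copy(),
        snapshot_steps=np.concatenate(all_steps) if all_steps else np.empty(0, dtype=np.int64),
        positions=np.concatenate(all_snaps) if all_snaps else np.empty((0, config.n_beads, 3), dtype=np.float32),
        log=log, final=config, surfactant_kind=kind,
    )
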