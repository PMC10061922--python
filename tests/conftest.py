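"""Shared fixtures: synthetic snapshots and small pre-equilibrated systems."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from emultrans.cg_system import (
    HS, HD, O, T, W,
    Configuration,
    Stage,
    SystemComposition,
    build_initial_configuration,
    default_interaction_matrix,
)
from emultrans.md_engine import Trajectory, run_simulation


def make_snapshot(
    species_z: list[tuple[int, np.ndarray]],
    box=(10.0, 10.0, 40.0),
    seed: int = 0,
) -> Configuration:
    """Synthetic single-bead-molecule snapshot from per-species z positions.

    ``species_z`` is a list of (species_code, z_array); x/y are uniform
    random.  Every bead is its own molecule (no bonds).
    """
    rng = np.random.default_rng(seed)
    species, zs = [], []
    for code, z in species_z:
        species += [code] * len(z)
        zs.append(np.asarray(z, dtype=float))
    z = np.concatenate(zs)
    n = len(z)
    pos = np.column_stack([
        rng.uniform(0, box[0], n), rng.uniform(0, box[1], n), z])
    return Configuration(
        positions=pos, velocities=np.zeros((n, 3)),
        species=np.array(species, dtype=np.int8),
        bonds=np.empty((0, 2), dtype=np.int64),
        molecule_id=np.arange(n, dtype=np.int64),
        box=np.array(box, dtype=float),
    )


def make_trajectory(positions_list, species, box, steps, molecule_id=None,
                    bonds=None) -> Trajectory:
    """Assemble an in-memory trajectory from a list of position arrays."""
    n = len(species)
    if molecule_id is None:
        molecule_id = np.arange(n, dtype=np.int64)
    if bonds is None:
        bonds = np.empty((0, 2), dtype=np.int64)
    pos = np.stack(positions_list).astype(np.float32)
    box = np.asarray(box, dtype=float)
    final = Configuration(
        positions_list[-1], np.zeros((n, 3)),
        np.asarray(species, dtype=np.int8), bonds,
        np.asarray(molecule_id, dtype=np.int64), box)
    return Trajectory(
        species=np.asarray(species, dtype=np.int8),
        molecule_id=np.asarray(molecule_id, dtype=np.int64),
        bonds=bonds, box=box,
        snapshot_steps=np.asarray(steps, dtype=np.int64),
        positions=pos, log=pd.DataFrame(), final=final)


@pytest.fixture(scope="session")
def binary_fluid_500() -> Configuration:
    """A 500-bead water/oil mixture (no bonds) for conservation tests.

    Bond-free on purpose: the stiff FENE+WCA core limits NVE energy
    conservation at the production time step (verified separately by a
    dt-convergence test on an isolated dimer), while the liquid mixture
    isolates the symplecticity of the nonbonded engine.
    """
    comp = SystemComposition(box=(7.2, 7.2, 14.6), n_surfactant=0, n_dye=0)
    return build_initial_configuration(comp, seed=42)


@pytest.fixture(scope="session")
def mixed_fluid_500() -> Configuration:
    """A 500-bead water/oil/surfactant/dye configuration for engine tests."""
    comp = SystemComposition(
        box=(7.2, 7.2, 14.6), density=0.66, surfactant_kind="short",
        n_surfactant=20, n_dye=8)
    assert 495 <= comp.total_beads <= 505
    return build_initial_configuration(comp, seed=42)


@pytest.fixture(scope="session")
def equilibrated_slab() -> tuple[Configuration, str]:
    """A small surfactant-decorated slab relaxed long enough for analysis tests.

    Built from the prepared-interface generator and relaxed for 2e4 steps
    with the dye held out of the oil (the interface-forming stage of the
    protocol).
    """
    from emultrans.synthetic_data import _build_prepared_interface

    # denser interfacial coverage than volume scaling would give, so the
    # surfactant-density maxima are unambiguous
    comp = SystemComposition(box=(8.0, 8.0, 24.0), surfactant_kind="short",
                             n_surfactant=40, n_dye=12)
    config = _build_prepared_interface(comp, seed=7)
    schedule = [Stage(
        "relax", 10_000,
        interaction_overrides=(("Hd", "O", None, "WCA"),
                               ("T", "O", None, "WCA")))]
    traj = run_simulation(config, schedule, snapshot_interval=10_000,
                          surfactant_kind="short", warmup_steps=2000)
    return traj.final, "short"
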