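"""Trajectory observables for the slab-geometry emulsion simulations.

The analyses quantify where molecules sit relative to the two liquid-liquid
interfaces of the periodic slab: interface location from the surfactant
headgroup density, per-molecule phase assignment, DBSCAN micelle detection in
the aqueous phase, the water/oil dye concentration difference and its
exponential relaxation time, and z/radial density profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from sklearn.cluster import DBSCAN

from .cg_system import HS, HD, O, T, W, Configuration, SPECIES
from .md_engine import Trajectory

__all__ = [
    "DensityProfile", "MicelleCluster", "TransportSeriesSim",
    "interface_positions", "assign_phase", "micelle_clusters",
    "concentration_difference_series", "fit_sim_decay",
    "dye_z_profile", "micelle_radial_profiles", "average_radial_profiles",
    "AnalysisError", "FitError",
]

DEFAULT_BIN_WIDTH = 0.5
INTERFACE_MARGIN = 3.0


class AnalysisError(ValueError):
    """The requested observable is undefined for this input."""


class FitError(RuntimeError):
    """A model fit failed or the data do not support the model."""


# ---------------------------------------------------------------------------
# small periodic helpers
# ---------------------------------------------------------------------------

def periodic_delta(a: np.ndarray, b: np.ndarray, length: float) -> np.ndarray:
    """Minimum-image difference a-b on a periodic axis of the given length."""
    d = a - b
    return d - length * np.round(d / length)


def circular_mean(x: np.ndarray, length: float) -> float:
    """Periodic-aware mean of coordinates on [0, length)."""
    theta = 2.0 * np.pi * np.asarray(x) / length
    mean = np.arctan2(np.sin(theta).mean(), np.cos(theta).mean())
    return float((mean / (2.0 * np.pi) * length) % length)


def _z_histogram(z: np.ndarray, lz: float, bin_width: float) -> tuple[np.ndarray, np.ndarray]:
    nbins = max(int(round(lz / bin_width)), 1)
    counts, edges = np.histogram(z % lz, bins=nbins, range=(0.0, lz))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return counts.astype(float), centers


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class DensityProfile:
    """Per-species number density against z (or scaled radius)."""

    bin_centers: np.ndarray
    density: dict[str, np.ndarray]
    bin_width: float
    normalized: bool = False
    interfacial_excess: float | None = None


@dataclass
class MicelleCluster:
    """A DBSCAN aggregate of solute/oil beads in the aqueous phase."""

    member_indices: np.ndarray
    center_of_mass: np.ndarray
    radius: float  # R_mic
    composition: dict[str, int]

    @property
    def size(self) -> int:
        return len(self.member_indices)


@dataclass
class TransportSeriesSim:
    """Dye concentration difference between water and oil along a trajectory.

    ``delta_c`` is (dye molecules per unit water volume) minus (per unit oil
    volume); ``delta_c_norm`` rescales it to run from 1 at the first analyzed
    snapshot to 0 at the last.
    """

    times: np.ndarray
    delta_c: np.ndarray
    delta_c_norm: np.ndarray
    degenerate: bool = False
    fit_lambda: float | None = None


# ---------------------------------------------------------------------------
# interfaces and phase assignment
# ---------------------------------------------------------------------------

def interface_positions(
    snapshot: Configuration,
    bin_width: float = DEFAULT_BIN_WIDTH,
    noise_z_score: float = 4.0,
) -> tuple[float, float]:
    """Locate the two interfaces from the surfactant-headgroup density maxima.

    The slab has two interfaces; the positions are the z bins where the Hs
    density peaks, one in each half of the box relative to the global
    maximum (periodic image handled).  Without surfactant the crossing point
    of the water and oil density profiles is used instead (a warning flags
    the fallback), as it is when the Hs profile has no peak above the noise
    floor of a uniform distribution.
    """
    lz = float(snapshot.box[2])
    z = snapshot.positions[:, 2]
    hs_mask = snapshot.species == HS
    if hs_mask.sum() > 0:
        counts, centers = _z_histogram(z[hs_mask], lz, bin_width)
        mean = counts.mean()
        # noise floor: a flat (surfactant-free-interface) profile fluctuates
        # around its mean with Poisson spread
        if counts.max() > mean + noise_z_score * np.sqrt(max(mean, 0.5)):
            i1 = int(np.argmax(counts))
            far = np.abs(periodic_delta(centers, centers[i1], lz)) > lz / 4.0
            if not np.any(far):
                raise AnalysisError("box too thin to hold two interfaces")
            cand = np.where(far)[0]
            i2 = cand[np.argmax(counts[cand])]
            z1, z2 = (
                _refine_peak(counts, centers, i, lz, bin_width)
                for i in (i1, i2)
            )
            return (min(z1, z2), max(z1, z2))
        warnings.warn(
            "surfactant density has no clear maxima (ambiguous interfaces); "
            "falling back to the solvent-density crossing", stacklevel=2)
    else:
        warnings.warn(
            "no surfactant beads; using the solvent-density crossing",
            stacklevel=2)
    return _solvent_crossings(snapshot, bin_width)


def _refine_peak(counts, centers, i_max, lz, bin_width, half_width=1.5):
    """Mass-weighted centroid of the bins around a histogram maximum."""
    rel = periodic_delta(centers, centers[i_max], lz)
    near = np.abs(rel) <= half_width
    w = counts[near]
    if w.sum() == 0:
        return float(centers[i_max])
    return float((centers[i_max] + np.sum(rel[near] * w) / w.sum()) % lz)


def _solvent_crossings(
    snapshot: Configuration, bin_width: float = DEFAULT_BIN_WIDTH
) -> tuple[float, float]:
    """Interface estimate from where the water and oil densities cross."""
    lz = float(snapshot.box[2])
    z = snapshot.positions[:, 2]
    w_counts, centers = _z_histogram(z[snapshot.species == W], lz, bin_width)
    o_counts, _ = _z_histogram(z[snapshot.species == O], lz, bin_width)
    diff = w_counts - o_counts
    # 3-bin periodic smoothing: sparse histograms otherwise produce
    # zero-count bins that hide the crossing
    diff = (diff + np.roll(diff, 1) + np.roll(diff, -1)) / 3.0
    sign = np.sign(diff)
    # carry the last non-zero sign through exact ties
    n = len(sign)
    nz = np.nonzero(sign)[0]
    if len(nz) == 0:
        raise AnalysisError("water and oil densities are indistinguishable")
    last = sign[nz[-1]]
    for i in range(n):
        if sign[i] == 0:
            sign[i] = last
        else:
            last = sign[i]
    crossings = []
    for i in range(n):
        j = (i + 1) % n
        if sign[i] != sign[j]:
            # linear interpolation of the zero crossing between bin centers
            zi = centers[i]
            denom = diff[i] - diff[j]
            frac = diff[i] / denom if denom != 0 else 0.5
            crossings.append((zi + frac * bin_width) % lz)
    if len(crossings) < 2:
        raise AnalysisError("could not locate two solvent-density crossings")
    if len(crossings) > 2:
        # keep the two crossings with the steepest density change
        steep = []
        for c in crossings:
            i = int(c / bin_width) % n
            steep.append(abs(diff[i] - diff[(i + 1) % n]))
        keep = np.argsort(steep)[-2:]
        crossings = [crossings[k] for k in sorted(keep)]
    z1, z2 = sorted(crossings)
    return (z1, z2)


def _head_bead_indices(snapshot: Configuration) -> tuple[np.ndarray, np.ndarray]:
    """First bead of every molecule (the head for chains), with molecule ids."""
    order = np.argsort(snapshot.molecule_id, kind="stable")
    mol_sorted = snapshot.molecule_id[order]
    first = np.ones(len(order), dtype=bool)
    first[1:] = mol_sorted[1:] != mol_sorted[:-1]
    heads = order[first]
    return heads, snapshot.molecule_id[heads]


def _distance_to_interfaces(z, interfaces, lz):
    d1 = np.abs(periodic_delta(z, interfaces[0], lz))
    d2 = np.abs(periodic_delta(z, interfaces[1], lz))
    return np.minimum(d1, d2)


def _oil_side(snapshot: Configuration, interfaces: tuple[float, float]) -> bool:
    """True if the oil slab lies between the two interface planes."""
    lz = float(snapshot.box[2])
    z_oil = snapshot.positions[snapshot.species == O, 2] % lz
    if len(z_oil) == 0:
        raise AnalysisError("no oil beads to orient the phases")
    between = (z_oil > interfaces[0]) & (z_oil < interfaces[1])
    return bool(between.mean() > 0.5)


def assign_phase(
    snapshot: Configuration,
    interfaces: tuple[float, float],
    margin: float = INTERFACE_MARGIN,
) -> np.ndarray:
    """Label every molecule 'water', 'oil' or 'interfacial' by its head bead.

    A molecule within ``margin`` of either interface plane is interfacial;
    otherwise the side of its head bead (first bead: Hd for the dye, Hs for
    surfactants) decides.  Head-bead assignment reflects that the headgroup
    sets the solubility of an amphiphile.
    """
    lz = float(snapshot.box[2])
    heads, mols = _head_bead_indices(snapshot)
    z = snapshot.positions[heads, 2] % lz
    dist = _distance_to_interfaces(z, interfaces, lz)
    between = (z > interfaces[0]) & (z < interfaces[1])
    oil_between = _oil_side(snapshot, interfaces)
    labels = np.where(between == oil_between, "oil", "water").astype(object)
    labels[dist < margin] = "interfacial"
    return labels


# ---------------------------------------------------------------------------
# micelles
# ---------------------------------------------------------------------------

def _periodic_distance_matrix(pos: np.ndarray, box: np.ndarray) -> np.ndarray:
    d2 = np.zeros((len(pos), len(pos)))
    for k in range(3):
        d = pos[:, k][:, None] - pos[:, k][None, :]
        d -= box[k] * np.round(d / box[k])
        d2 += d * d
    return np.sqrt(d2)


def micelle_clusters(
    snapshot: Configuration,
    interfaces: tuple[float, float],
    eps: float = 1.3,
    min_samples: int = 4,
    margin: float = INTERFACE_MARGIN,
) -> list[MicelleCluster]:
    """DBSCAN aggregates of O/T/Hs/Hd beads in the bulk aqueous phase.

    Only beads at least ``margin`` from both interfaces and on the water side
    count, so detected micelles do not touch the interface.  Distances use
    the periodic minimum image; cluster centers come from per-axis circular
    means and ``R_mic`` is the radius of gyration scaled to the equivalent
    uniform-sphere radius, ``sqrt(5/3) R_g``.
    """
    if eps <= 0 or min_samples < 1:
        raise AnalysisError("eps must be > 0 and min_samples >= 1")
    lz = float(snapshot.box[2])
    z = snapshot.positions[:, 2] % lz
    eligible_species = np.isin(snapshot.species, [O, T, HS, HD])
    dist = _distance_to_interfaces(z, interfaces, lz)
    between = (z > interfaces[0]) & (z < interfaces[1])
    water_side = between != _oil_side(snapshot, interfaces)
    mask = eligible_species & water_side & (dist >= margin)
    idx = np.where(mask)[0]
    if len(idx) == 0:
        return []
    pos = snapshot.positions[idx] % snapshot.box
    dmat = _periodic_distance_matrix(pos, snapshot.box)
    labels = DBSCAN(eps=eps, min_samples=min_samples, metric="precomputed").fit(
        dmat).labels_
    clusters = []
    for lab in sorted(set(labels) - {-1}):
        members = idx[labels == lab]
        mpos = snapshot.positions[members] % snapshot.box
        com = np.array([
            circular_mean(mpos[:, k], snapshot.box[k]) for k in range(3)
        ])
        rel = np.column_stack([
            periodic_delta(mpos[:, k], com[k], snapshot.box[k]) for k in range(3)
        ])
        rg2 = float(np.mean(np.sum(rel**2, axis=1)))
        comp = {
            SPECIES[s]: int(np.sum(snapshot.species[members] == s))
            for s in (O, T, HS, HD)
        }
        clusters.append(MicelleCluster(
            member_indices=members, center_of_mass=com,
            radius=float(np.sqrt(5.0 / 3.0 * rg2)), composition=comp,
        ))
    clusters.sort(key=lambda c: -c.size)
    return clusters


# ---------------------------------------------------------------------------
# dye transport
# ---------------------------------------------------------------------------

def concentration_difference_series(
    trajectory: Trajectory,
    exclude_before: int | None = None,
    margin: float = INTERFACE_MARGIN,
    interfaces: tuple[float, float] | None = None,
) -> TransportSeriesSim:
    """Water/oil dye concentration difference over the analyzed snapshots.

    Early snapshots (default: anything before one tenth of the trajectory
    span, emulating the exclusion of the initial micelle-formation window)
    are dropped.  Phase volumes are the fixed half-boxes minus the
    interfacial margin shells; dye molecules in the margins count toward
    neither phase.  The normalized series is anchored to 1 at the first
    analyzed snapshot and 0 at the last.
    """
    steps = trajectory.snapshot_steps
    if len(steps) < 2:
        raise AnalysisError("need at least two snapshots")
    if exclude_before is None:
        exclude_before = int(steps[-1] * 0.1) if steps[-1] > 10 else 0
    keep = steps >= exclude_before
    if keep.sum() < 2:
        raise AnalysisError("exclusion window leaves fewer than two snapshots")

    area = trajectory.box[0] * trajectory.box[1]
    half = trajectory.box[2] / 2.0
    vol = area * (half - 2.0 * margin)  # each phase loses a shell per interface
    if vol <= 0:
        raise AnalysisError("interfacial margin consumes an entire phase")

    times, dc = [], []
    for i in np.where(keep)[0]:
        snap = trajectory.snapshot(i)
        ifaces = interfaces if interfaces is not None else interface_positions(snap)
        labels = assign_phase(snap, ifaces, margin)
        is_dye = snap.species[_head_bead_indices(snap)[0]] == HD
        n_w = int(np.sum((labels == "water") & is_dye))
        n_o = int(np.sum((labels == "oil") & is_dye))
        times.append(steps[i])
        dc.append(n_w / vol - n_o / vol)
    times = np.asarray(times, dtype=float)
    dc = np.asarray(dc)
    span = dc[0] - dc[-1]
    degenerate = abs(span) < 1e-12
    if degenerate:
        warnings.warn("concentration difference does not decay", stacklevel=2)
        norm = np.ones_like(dc)
    else:
        norm = (dc - dc[-1]) / span
    return TransportSeriesSim(times, dc, norm, degenerate=degenerate)


def fit_sim_decay(series: TransportSeriesSim) -> tuple[float, float]:
    """Fit exp(-t/lambda) to the normalized concentration difference.

    Times are measured from the first analyzed snapshot.  Returns
    ``(lambda, rmse)``; raises :class:`FitError` for degenerate or
    non-decaying series.
    """
    if len(series.times) < 5:
        raise FitError("need at least 5 time points")
    if series.degenerate:
        raise FitError("series does not decay; lambda is undefined")
    t = series.times - series.times[0]
    y = series.delta_c_norm
    if y[: max(2, len(y) // 5)].mean() <= y[-max(2, len(y) // 5):].mean():
        raise FitError("series is not decaying on average")
    # log-linear initialization on the positive part
    pos = y > 0.05
    slope = np.polyfit(t[pos], np.log(y[pos]), 1)[0] if pos.sum() >= 2 else -1.0 / t[-1]
    lam0 = -1.0 / slope if slope < 0 else t[-1]
    try:
        popt, _ = curve_fit(
            lambda tt, lam: np.exp(-tt / lam), t, y, p0=[max(lam0, t[1])],
            bounds=(t[1] * 1e-3, t[-1] * 1e3), maxfev=10000)
    except RuntimeError as exc:
        raise FitError(f"exponential fit did not converge: {exc}") from exc
    lam = float(popt[0])
    rmse = float(np.sqrt(np.mean((np.exp(-t / lam) - y) ** 2)))
    return lam, rmse


# ---------------------------------------------------------------------------
# density profiles
# ---------------------------------------------------------------------------

def dye_z_profile(
    trajectory: Trajectory,
    window: tuple[int, int] | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    interfaces: tuple[float, float] | None = None,
) -> DensityProfile:
    """Time-averaged dye-bead density along z, normalized by its mean.

    ``window`` selects snapshots by global step index (inclusive range).
    ``interfacial_excess`` reports the peak density within 2 sigma of an
    interface relative to the bulk level, a measure of dye accumulation at
    the interface.
    """
    steps = trajectory.snapshot_steps
    if window is None:
        sel = np.arange(len(steps))
    else:
        sel = np.where((steps >= window[0]) & (steps <= window[1]))[0]
    if len(sel) == 0:
        raise AnalysisError("empty snapshot window")
    lz = float(trajectory.box[2])
    nbins = max(int(round(lz / bin_width)), 1)
    width = lz / nbins
    dye_beads = np.isin(trajectory.species, [HD]) | (
        (trajectory.species == T)
        & np.isin(trajectory.molecule_id,
                  trajectory.molecule_id[trajectory.species == HD])
    )
    counts = np.zeros(nbins)
    for i in sel:
        z = trajectory.positions[i, dye_beads, 2].astype(float) % lz
        counts += np.histogram(z, bins=nbins, range=(0.0, lz))[0]
    area = trajectory.box[0] * trajectory.box[1]
    density = counts / (len(sel) * area * width)
    centers = (np.arange(nbins) + 0.5) * width

    mean = density.mean()
    norm = density / mean if mean > 0 else density
    excess = None
    if mean > 0:
        snap = trajectory.snapshot(sel[-1])
        try:
            ifaces = interfaces if interfaces is not None else interface_positions(snap)
            near = _distance_to_interfaces(centers, ifaces, lz) <= 2.0
            if near.any():
                excess = float(norm[near].max())
        except (AnalysisError, Warning):
            pass
    return DensityProfile(centers, {"dye": norm}, width, normalized=True,
                          interfacial_excess=excess)


def average_radial_profiles(
    profiles: list[DensityProfile],
) -> tuple[DensityProfile, dict[str, np.ndarray]]:
    """Mean radial profile over clusters/runs with standard-error bands.

    All inputs must share the same scaled binning.  Returns the averaged
    profile and a dict of per-species standard errors of the mean.
    """
    if not profiles:
        raise AnalysisError("no profiles to average")
    ref = profiles[0]
    for p in profiles[1:]:
        if len(p.bin_centers) != len(ref.bin_centers) or \
                p.bin_width != ref.bin_width:
            raise AnalysisError("profiles must share a common binning")
    names = ref.density.keys()
    mean, sem = {}, {}
    n = len(profiles)
    for name in names:
        stack = np.vstack([p.density[name] for p in profiles])
        mean[name] = stack.mean(axis=0)
        sem[name] = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 \
            else np.zeros(stack.shape[1])
    return DensityProfile(ref.bin_centers.copy(), mean, ref.bin_width), sem


def micelle_radial_profiles(
    cluster: MicelleCluster,
    snapshot: Configuration,
    bin_width_scaled: float = 0.1,
    r_max_scaled: float = 2.0,
) -> DensityProfile:
    """Spherically averaged species densities around a micelle center.

    The abscissa is the radial distance from the cluster's center of mass
    scaled by the micelle radius ``R_mic``; densities are absolute number
    densities (sigma^-3) computed in spherical shells, species split by the
    molecule type the bead belongs to (dye, oil, surfactant).
    """
    if cluster.size < 2:
        raise AnalysisError("radial profile undefined for single-bead clusters")
    box = snapshot.box
    rel = np.column_stack([
        periodic_delta(snapshot.positions[:, k] % box[k],
                       cluster.center_of_mass[k], box[k])
        for k in range(3)
    ])
    r = np.linalg.norm(rel, axis=1)
    rmic = cluster.radius
    if rmic <= 0:
        raise AnalysisError("cluster has zero radius")
    nbins = int(round(r_max_scaled / bin_width_scaled))
    edges = np.arange(nbins + 1) * bin_width_scaled * rmic
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)

    dye_mols = set(snapshot.molecule_id[snapshot.species == HD].tolist())
    surf_mols = set(snapshot.molecule_id[snapshot.species == HS].tolist())
    mol = snapshot.molecule_id
    groups = {
        "dye": np.isin(mol, list(dye_mols)),
        "oil": snapshot.species == O,
        "surfactant": np.isin(mol, list(surf_mols)),
    }
    density = {}
    for name, gmask in groups.items():
        counts, _ = np.histogram(r[gmask], bins=edges)
        density[name] = counts / shell_vol
    centers = (np.arange(nbins) + 0.5) * bin_width_scaled
    return DensityProfile(centers, density, bin_width_scaled, normalized=False)
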