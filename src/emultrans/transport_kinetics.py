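"""Kinetic models for solute uptake and exchange in oil-in-water emulsions.

A lipophilic solute loaded into the continuous (micellar) phase of an
emulsion equilibrates with the dispersed oil droplets.  The concentration
difference between the phases, ``dc = c_w - c_o``, relaxes exponentially with
a droplet-size-dependent time scale; permeability theory relates that time
scale to the droplet volume-to-surface ratio, ``lambda = V/(S P)``, which for
spheres means ``lambda`` grows linearly with diameter with slope
``1/(6 P)``.  Once the continuous phase is depleted, solute is redistributed
between droplets of different size, producing a rise-then-decay of the
droplet-to-droplet concentration difference ``dC`` described by a
two-timescale model ``dC(t) = A (exp(-t/lambda2) - exp(-t/lambda1))``.

Working units follow the experiments: diameters in micrometres, times in
minutes, permeabilities in m/s, concentrations in arbitrary
(extinction-corrected) intensity units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import constants
from scipy.optimize import curve_fit
from scipy.stats import linregress

__all__ = [
    "DropletRecord", "ExchangeFit", "TwoTimescaleFit", "PermeabilityEstimate",
    "bin_by_droplet_size", "fit_eq2", "collapse_master_curve", "fit_eq3",
    "permeability_from_lambda_slope", "predicted_micellar_permeability",
    "stokes_einstein_diffusivity", "eq3_peak_time",
    "KineticsError", "FitError",
    "MINUTES_PER_SECOND", "METERS_PER_MICRON",
]

METERS_PER_MICRON = 1e-6
SECONDS_PER_MINUTE = 60.0
MINUTES_PER_SECOND = 1.0 / SECONDS_PER_MINUTE

RECORD_COLUMNS = ("droplet_id", "t_min", "d_um", "c_oil", "c_water")


class KineticsError(ValueError):
    """Invalid input for a kinetic analysis."""


class FitError(RuntimeError):
    """A kinetic model fit failed."""


@dataclass
class DropletRecord:
    """One droplet observation: size, time, and phase concentrations."""

    droplet_id: int
    t_min: float
    d_um: float
    c_oil: float
    c_water: float

    def __post_init__(self) -> None:
        if self.d_um <= 0:
            raise KineticsError("droplet diameter must be positive")
        if self.t_min < 0:
            raise KineticsError("time must be non-negative")
        if self.c_oil < 0 or self.c_water < 0:
            raise KineticsError("concentrations must be non-negative")

    @property
    def delta_c(self) -> float:
        return self.c_water - self.c_oil


@dataclass
class ExchangeFit:
    """Single-exponential exchange fit dc(t) = dc_inf + (dc0-dc_inf) e^(-t/lambda)."""

    delta_c0: float
    delta_c_inf: float
    lam: float  # minutes
    rmse: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise FitError("exchange time scale must be positive")

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return self.delta_c_inf + (self.delta_c0 - self.delta_c_inf) * np.exp(
            -(np.asarray(t) - self.t0) / self.lam)


@dataclass
class TwoTimescaleFit:
    """Two-timescale uptake/exchange fit dC(t) = A (e^(-t/l2) - e^(-t/l1))."""

    lambda1: float  # uptake, minutes
    lambda2: float  # inter-droplet exchange, minutes
    amplitude: float
    rmse: float

    def __post_init__(self) -> None:
        if not 0 < self.lambda1 < self.lambda2:
            raise FitError("two-timescale fit requires 0 < lambda1 < lambda2")

    @property
    def t_max(self) -> float:
        """Analytic location of the maximum of the model."""
        return eq3_peak_time(self.lambda1, self.lambda2)

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t)
        return self.amplitude * (np.exp(-t / self.lambda2) - np.exp(-t / self.lambda1))


@dataclass
class PermeabilityEstimate:
    """Interfacial permeability from the slope of lambda(d)."""

    permeability: float  # m/s
    lambda0: float  # minutes, intercept
    slope: float  # minutes per micron
    r_squared: float

    def __post_init__(self) -> None:
        if self.permeability <= 0:
            raise FitError("permeability must be positive")


# ---------------------------------------------------------------------------
# droplet-size binning
# ---------------------------------------------------------------------------

def bin_by_droplet_size(
    records: pd.DataFrame,
    n_bins: int = 4,
    edges: np.ndarray | None = None,
) -> list[dict]:
    """Split droplet records into size classes and average dc(t) per class.

    Default binning is equal-count quartiles of the droplet diameters
    (per unique droplet); fixed ``edges`` may be passed instead.  Returns one
    dict per non-empty bin with keys ``mean_diameter`` (unweighted mean over
    droplets), ``t_min``, ``delta_c`` (mean over droplets at each time) and
    ``n_droplets``.  Empty bins trigger re-binning to the non-empty classes
    with a warning.
    """
    df = _as_records_frame(records)
    sizes = df.groupby("droplet_id")["d_um"].first()
    if sizes.nunique() < n_bins:
        warnings.warn(
            f"only {sizes.nunique()} distinct diameters for {n_bins} bins; "
            "using one bin per distinct size", stacklevel=2)
        n_bins = max(sizes.nunique(), 1)
    if edges is None:
        qs = np.linspace(0, 1, n_bins + 1)
        edges = np.unique(np.quantile(sizes, qs))
        if edges.size < 2:  # all diameters identical
            edges = np.array([edges[0] - 0.5, edges[0] + 0.5])
    edges = np.asarray(edges, dtype=float)
    edges[-1] = np.nextafter(edges[-1], np.inf)
    labels = np.digitize(sizes, edges) - 1
    labels = np.clip(labels, 0, len(edges) - 2)
    bin_of = dict(zip(sizes.index, labels))
    df = df.assign(size_bin=df["droplet_id"].map(bin_of))

    out = []
    for b in range(len(edges) - 1):
        sub = df[df["size_bin"] == b]
        if sub.empty:
            warnings.warn(f"size bin {b} is empty; skipped", stacklevel=2)
            continue
        mean_d = float(sizes[labels == b].mean())
        series = sub.assign(delta_c=sub["c_water"] - sub["c_oil"]) \
            .groupby("t_min")["delta_c"].mean()
        out.append({
            "mean_diameter": mean_d,
            "t_min": series.index.to_numpy(dtype=float),
            "delta_c": series.to_numpy(),
            "n_droplets": int((labels == b).sum()),
        })
    return out


def _as_records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        missing = set(RECORD_COLUMNS) - set(records.columns)
        if missing:
            raise KineticsError(f"records missing columns {sorted(missing)}")
        return records
    return pd.DataFrame([vars(r) for r in records])


# ---------------------------------------------------------------------------
# exponential exchange fit
# ---------------------------------------------------------------------------

def fit_eq2(t_min: np.ndarray, delta_c: np.ndarray) -> ExchangeFit:
    """Fit the single-exponential relaxation of the phase concentration difference.

    ``dc(t) = dc_inf + (dc0 - dc_inf) exp(-(t - t0)/lambda)`` with ``t0`` the
    first observation time.  Raises :class:`FitError` when the series carries
    no decay (lambda unidentifiable) or the optimizer fails.
    """
    t = np.asarray(t_min, dtype=float)
    y = np.asarray(delta_c, dtype=float)
    if len(t) < 5:
        raise FitError("need at least 5 points for the exchange fit")
    t0 = t[0]
    span = y[0] - y[-1]
    if abs(span) < 1e-12 * max(abs(y[0]), 1.0) or np.ptp(y) < 1e-12:
        raise FitError("delta_c0 equals delta_c_inf: lambda is unidentifiable")

    def model(tt, c0, cinf, lam):
        return cinf + (c0 - cinf) * np.exp(-(tt - t0) / lam)

    dt = max(t[-1] - t0, 1.0)
    lam0 = dt / 3.0
    try:
        popt, _ = curve_fit(
            model, t, y, p0=[y[0], y[-1], lam0],
            bounds=([-np.inf, -np.inf, dt * 1e-6], [np.inf, np.inf, dt * 1e4]),
            maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"exchange fit did not converge: {exc}") from exc
    rmse = float(np.sqrt(np.mean((model(t, *popt) - y) ** 2)))
    return ExchangeFit(float(popt[0]), float(popt[1]), float(popt[2]), rmse, t0)


def collapse_master_curve(
    fits: list[ExchangeFit],
    series_list: list[tuple[np.ndarray, np.ndarray]],
    grid_size: int = 50,
) -> dict:
    """Rescale each series to (dc-dc_inf)/(dc0-dc_inf) against t/lambda.

    All size classes should fall on the single master curve exp(-t/lambda);
    the collapse score is the maximum spread between series interpolated on a
    common reduced-time grid (0 for a perfect collapse).  Series without a
    fit (None) are excluded with a warning.
    """
    rescaled = []
    for fit, (t, y) in zip(fits, series_list):
        if fit is None:
            warnings.warn("series without a successful fit excluded from "
                          "the master curve", stacklevel=2)
            continue
        span = fit.delta_c0 - fit.delta_c_inf
        rescaled.append((
            (np.asarray(t) - fit.t0) / fit.lam,
            (np.asarray(y) - fit.delta_c_inf) / span,
        ))
    if not rescaled:
        raise FitError("no successfully fitted series to collapse")
    tmax = min(ts.max() for ts, _ in rescaled)
    grid = np.linspace(0, tmax, grid_size)
    interp = np.vstack([np.interp(grid, ts, ys) for ts, ys in rescaled])
    score = float(np.max(interp.max(axis=0) - interp.min(axis=0))) \
        if len(interp) > 1 else 0.0
    return {"rescaled": rescaled, "grid": grid, "curves": interp,
            "collapse_score": score}


# ---------------------------------------------------------------------------
# two-timescale uptake/exchange model
# ---------------------------------------------------------------------------

def eq3_peak_time(lambda1: float, lambda2: float) -> float:
    """Peak position of A(e^(-t/l2) - e^(-t/l1)): (l1 l2/(l2-l1)) ln(l2/l1)."""
    if not 0 < lambda1 < lambda2:
        raise KineticsError("peak time requires 0 < lambda1 < lambda2")
    return lambda1 * lambda2 / (lambda2 - lambda1) * np.log(lambda2 / lambda1)


def fit_eq3(
    t_min: np.ndarray, delta_C: np.ndarray, n_starts: int = 8
) -> TwoTimescaleFit:
    """Fit the rise-and-decay of the droplet-to-droplet concentration difference.

    The model ``dC(t) = A (exp(-t/lambda2) - exp(-t/lambda1))`` rises from
    zero on the uptake time scale lambda1 (depletion of the continuous
    phase), peaks, and relaxes on the slower inter-droplet exchange time
    scale lambda2.  The fit is multi-started from a log-spaced grid of
    timescale pairs because the loss surface is multimodal.  Monotone series
    (peak at either end) are rejected.
    """
    t = np.asarray(t_min, dtype=float)
    y = np.asarray(delta_C, dtype=float)
    if len(t) < 5:
        raise FitError("need at least 5 points for the two-timescale fit")
    ipk = int(np.argmax(np.abs(y)))
    if ipk == 0 or ipk == len(y) - 1:
        raise FitError(
            "series is monotone (no interior peak); the two-timescale model "
            "does not apply")

    def model(tt, lam1, lam2, amp):
        return amp * (np.exp(-tt / lam2) - np.exp(-tt / lam1))

    tspan = t[-1] - t[0] if t[-1] > t[0] else 1.0
    lam_grid = np.geomspace(tspan * 1e-2, tspan * 10, n_starts)
    best = None
    ypk = y[ipk]
    for l1 in lam_grid:
        for l2 in lam_grid:
            if l2 <= l1 * 1.5:
                continue
            try:
                popt, _ = curve_fit(
                    model, t, y, p0=[l1, l2, ypk * 2],
                    bounds=([tspan * 1e-6, tspan * 1e-6, -np.inf],
                            [tspan * 1e4, tspan * 1e4, np.inf]),
                    maxfev=5000)
            except RuntimeError:
                continue
            sse = float(np.sum((model(t, *popt) - y) ** 2))
            if best is None or sse < best[0]:
                best = (sse, popt)
    if best is None:
        raise FitError("two-timescale fit did not converge from any start")
    sse, (l1, l2, amp) = best
    if l1 > l2:  # the model is symmetric under (l1,l2,A) -> (l2,l1,-A)
        l1, l2, amp = l2, l1, -amp
    if l2 <= l1 * (1 + 1e-6):
        raise FitError(
            "degenerate fit lambda1 == lambda2 (the model reduces to "
            "t exp(-t/lambda)); timescales are not separable")
    rmse = float(np.sqrt(sse / len(t)))
    return TwoTimescaleFit(float(l1), float(l2), float(amp), rmse)


# ---------------------------------------------------------------------------
# permeability
# ---------------------------------------------------------------------------

def permeability_from_lambda_slope(
    lambdas_min: np.ndarray, diameters_um: np.ndarray
) -> PermeabilityEstimate:
    """Permeability from the linear droplet-size dependence of lambda.

    ``lambda = lambda0 + d/(6 P)`` for spherical droplets (V/S = d/6); a
    linear fit of lambda against diameter gives P = 1/(6 slope) after
    converting microns/minutes to SI.  The intercept lambda0 is reported
    separately (it varies with surfactant concentration).
    """
    lam = np.asarray(lambdas_min, dtype=float)
    d = np.asarray(diameters_um, dtype=float)
    if len(lam) != len(d) or len(lam) < 3:
        raise KineticsError("need at least 3 (diameter, lambda) pairs")
    res = linregress(d, lam)
    if res.slope <= 0:
        raise FitError("lambda does not increase with droplet size; "
                       "permeability is undefined")
    slope_s_per_m = res.slope * SECONDS_PER_MINUTE / METERS_PER_MICRON
    return PermeabilityEstimate(
        permeability=1.0 / (6.0 * slope_s_per_m),
        lambda0=float(res.intercept),
        slope=float(res.slope),
        r_squared=float(res.rvalue**2),
    )


def predicted_micellar_permeability(
    partition_coefficient: float,
    micelle_diffusivity: float,
    interface_thickness: float,
) -> float:
    """Permeability if micellar diffusion across the interface were limiting.

    ``P = K D_m / l`` with the oil/water partition coefficient K, the
    micelle-aggregate diffusivity D_m (m^2/s) and the interface thickness l
    (m).  Comparing this with the measured permeability tests whether
    transport is diffusion- or interface-limited.
    """
    if partition_coefficient <= 0 or micelle_diffusivity <= 0 \
            or interface_thickness <= 0:
        raise KineticsError("all permeability inputs must be positive")
    return partition_coefficient * micelle_diffusivity / interface_thickness


def stokes_einstein_diffusivity(
    diameter_m: float, viscosity_pa_s: float, temperature_k: float = 298.0
) -> float:
    """Stokes-Einstein diffusivity D = kB T / (3 pi eta d) of a sphere."""
    if diameter_m <= 0 or viscosity_pa_s <= 0 or temperature_k <= 0:
        raise KineticsError("diameter, viscosity and temperature must be positive")
    return constants.k * temperature_k / (
        3.0 * np.pi * viscosity_pa_s * diameter_m)
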