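"""Carbon and phosphorus exchange fluxes from network morphology.

Carbon side: the carbon locked in the network is ``Ct = MC * (sum of edge
cylinder volumes + sum of spore sphere volumes)`` with ``MC = d_cell * f_dry
* f_carbon`` the carbon mass per unit cell volume; the expenditure rate is
``PhiC = (dCt/dt) / CUE`` where CUE is the carbon-use efficiency (default
50%, a typical soil-fungus value).  Maintenance respiration (proportional to
Ct) is neglected — PhiC is a leading-order growth cost.

Phosphorus side: uptake is limited by membrane transporters at a
characteristic surface density, so the compartment P mass obeys
``dPf/dt = -J([P]) * S`` with Michaelis-Menten ``J([P]) = Jmax [P]/([P]+Km)``.
While transporters stay saturated this integrates to ``Pf(tm) = Pf(0) -
J * int_0^tm S dt``: the calibration regression recovers J as minus the
slope of Pf against the time-integrated surface area.  The P supply rate to
the host is then ``PhiP = J([P]) * S``, with the accessible pool tracked
self-consistently so depletion feeds back on [P].

Also here: the media-P accounting for the growth-medium recipe (KH2PO4 plus
the phosphorus contributed by the Phytagel gelling agent, minus the
adsorbed, inaccessible fraction), through-origin exchange-rate fits and
binned averages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._units import (
    HOURS_PER_DAY,
    ATOMIC_MASS_P,
    NG_PER_UG,
    P_MASS_FRACTION_KH2PO4,
    UG_PER_NG,
)
from .morphometry import NetworkSnapshot, network_totals

__all__ = [
    "CarbonParams",
    "TransportParams",
    "MediaPhosphorus",
    "CalibrationResult",
    "total_carbon",
    "carbon_flux",
    "integrated_surface",
    "calibrate_J",
    "phosphorus_flux",
    "media_phosphorus",
    "exchange_ratio_fit",
    "binned_average",
    "compute_flux_series",
]


@dataclass(frozen=True)
class CarbonParams:
    """Carbon bookkeeping constants.

    ``d_cell`` is the wet cell mass density, ``f_dry`` the dry-mass
    fraction, ``f_carbon`` the carbon fraction of dry mass; their product is
    the carbon mass per unit cell volume ``MC``.  The defaults are
    documented placeholders (MC for AM fungi is not directly measured);
    every flux carries them multiplicatively, so ratios rescale simply.
    """

    d_cell_g_per_cm3: float = 1.1
    f_dry: float = 0.25
    f_carbon: float = 0.45
    cue: float = 0.5

    def __post_init__(self) -> None:
        for name in ("f_dry", "f_carbon", "cue"):
            value = getattr(self, name)
            if not 0 < value <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {value}")
        if self.d_cell_g_per_cm3 <= 0:
            raise ValueError("d_cell must be positive")

    @property
    def MC_ug_per_mm3(self) -> float:
        # g/cm^3 == 1000 ug/mm^3
        return self.d_cell_g_per_cm3 * 1e3 * self.f_dry * self.f_carbon


@dataclass(frozen=True)
class TransportParams:
    """Phosphorus transport constants.

    ``J`` is the calibrated (saturated) areal uptake rate; ``Jmax``/``Km``
    parameterise the Michaelis-Menten concentration dependence.  The
    inaccessible concentration is the adsorbed baseline P that neither
    fungus nor root can extract.
    """

    J_ng_per_mm2_h: float = 3.0
    Jmax_ng_per_mm2_h: float = 3.0
    Km_ug_per_ml: float = 0.3
    inaccessible_conc_ug_per_ml: float = 2.0
    gel_volume_ml: float = 28.0
    gel_depth_mm: float = 2.5

    def __post_init__(self) -> None:
        for name in (
            "J_ng_per_mm2_h",
            "Jmax_ng_per_mm2_h",
            "Km_ug_per_ml",
            "inaccessible_conc_ug_per_ml",
            "gel_volume_ml",
            "gel_depth_mm",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.J_ng_per_mm2_h > self.Jmax_ng_per_mm2_h:
            raise ValueError("J cannot exceed Jmax")

    def rate_at(self, conc_ug_per_ml) -> np.ndarray:
        """J([P]) in ng mm^-2 h^-1 at an accessible concentration."""
        conc = np.maximum(np.asarray(conc_ug_per_ml, dtype=float), 0.0)
        if self.Km_ug_per_ml == 0:
            return np.where(conc > 0, self.Jmax_ng_per_mm2_h, 0.0)
        return self.Jmax_ng_per_mm2_h * conc / (conc + self.Km_ug_per_ml)


def total_carbon(snapshot: NetworkSnapshot, params: CarbonParams) -> float:
    """Carbon content Ct (ug) of a snapshot: MC x total cell volume."""
    return params.MC_ug_per_mm3 * network_totals(snapshot)["V_mm3"]


def carbon_flux(
    t_h,
    ct_ug,
    params: CarbonParams,
    smoothing_window_h: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Carbon expenditure rate PhiC (ug/h) from a Ct time series.

    Central finite differences of (optionally moving-average pre-smoothed)
    Ct, divided by CUE.  Negative derivatives — biomass cannot be un-built
    at leading order — are floored at 0 and flagged.

    Returns ``(phi_c, floored)`` where ``floored`` marks floored samples.
    """
    t = np.asarray(t_h, dtype=float)
    ct = np.asarray(ct_ug, dtype=float)
    if len(t) < 2:
        raise ValueError("need >= 2 timesteps for a derivative")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time vector must be strictly increasing")
    if smoothing_window_h and smoothing_window_h > 0:
        dt = np.median(np.diff(t))
        width = max(1, int(round(smoothing_window_h / dt)))
        if width > 1:
            kernel = np.ones(width) / width
            pad = width // 2
            padded = np.pad(ct, pad, mode="edge")
            ct = np.convolve(padded, kernel, mode="same")[pad:pad + len(t)]
    dct = np.gradient(ct, t)
    floored = dct < 0
    phi_c = np.maximum(dct, 0.0) / params.cue
    return phi_c, floored


def integrated_surface(t_h, s_mm2, t_m: float) -> float:
    """Trapezoidal ``int_0^tm S dt`` (mm^2 h) of a surface-area series.

    The series is assumed to start from S=0 at t=0 if its first sample is
    later; ``t_m`` may fall between samples (linear interpolation).
    """
    t = np.asarray(t_h, dtype=float)
    s = np.asarray(s_mm2, dtype=float)
    if t_m < t[0] and not np.isclose(t[0], 0.0) and t_m < 0:
        raise ValueError("t_m before the start of the series")
    if t[0] > 0:
        t = np.concatenate([[0.0], t])
        s = np.concatenate([[0.0], s])
    if t_m > t[-1] + 1e-9:
        raise ValueError(f"t_m={t_m} beyond the series end {t[-1]}")
    keep = t <= t_m
    tt = np.concatenate([t[keep], [t_m]])
    ss = np.concatenate([s[keep], [np.interp(t_m, t, s)]])
    return float(np.trapezoid(ss, tt))


@dataclass
class CalibrationResult:
    """Depletion-calibration fit of the areal uptake coefficient J."""

    J_ng_per_mm2_h: float
    ci_ng_per_mm2_h: tuple[float, float]
    r_squared: float
    Pf0_ug: float
    slope_ug_per_mm2h: float
    n_points: int
    no_depletion_signal: bool = False


def calibrate_J(
    assay: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> CalibrationResult:
    """Least-squares line of Pf against the time-integrated surface area.

    ``J`` is minus the slope (converted to ng mm^-2 h^-1); the confidence
    interval is a percentile bootstrap over assay rows.  A positive fitted
    slope (no depletion signal) is flagged with a warning.
    """
    x = assay["intS_mm2h"].to_numpy(float)
    y = assay["Pf_ug"].to_numpy(float)
    if len(x) < 3:
        raise ValueError("need >= 3 assay points")
    if np.ptp(x) == 0:
        raise ValueError("all integrated surface areas equal: singular design")
    fit = stats.linregress(x, y)
    no_signal = fit.slope > 0
    if no_signal:
        warnings.warn("positive fitted slope: no depletion signal", stacklevel=2)
    J = -fit.slope * NG_PER_UG
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    idx = np.arange(len(x))
    for b in range(n_boot):
        take = rng.choice(idx, size=len(idx), replace=True)
        if np.ptp(x[take]) == 0:
            boot[b] = np.nan
            continue
        boot[b] = -stats.linregress(x[take], y[take]).slope * NG_PER_UG
    alpha = (1.0 - ci_level) / 2.0
    ci = tuple(np.nanquantile(boot, [alpha, 1.0 - alpha]))
    return CalibrationResult(
        J_ng_per_mm2_h=float(J),
        ci_ng_per_mm2_h=(float(ci[0]), float(ci[1])),
        r_squared=float(fit.rvalue**2),
        Pf0_ug=float(fit.intercept),
        slope_ug_per_mm2h=float(fit.slope),
        n_points=len(x),
    )


def phosphorus_flux(
    t_h,
    s_mm2,
    transport: TransportParams,
    P_budget_ug: float,
) -> pd.DataFrame:
    """P supply rate PhiP(t) = J([P](t)) * S(t) with self-consistent depletion.

    ``P_budget_ug`` is the accessible P mass at t=0; the accessible
    concentration ``[P](t) = remaining / gel_volume`` is updated explicitly
    per timestep as P is transferred, so uptake slows (Michaelis-Menten) and
    finally stops as the pool empties.  Cumulative transfer never exceeds
    the budget.

    Returns columns ``t_h, S_mm2, conc_ug_per_ml, PhiP_ug_per_h,
    cum_P_ug``.
    """
    if P_budget_ug < 0:
        raise ValueError("P budget must be non-negative")
    t = np.asarray(t_h, dtype=float)
    s = np.asarray(s_mm2, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time vector must be strictly increasing")
    remaining = float(P_budget_ug)
    conc = np.empty(len(t))
    phi = np.empty(len(t))
    cum = np.empty(len(t))
    max_substep_h = 0.25
    for i in range(len(t)):
        conc[i] = remaining / transport.gel_volume_ml
        phi[i] = float(transport.rate_at(conc[i])) * s[i] * UG_PER_NG
        cum[i] = P_budget_ug - remaining
        if i < len(t) - 1:
            # advance the pool with sub-stepped explicit updates so the
            # reported series is accurate at coarse (2-h) sampling
            dt = t[i + 1] - t[i]
            n_sub = max(1, int(np.ceil(dt / max_substep_h)))
            h = dt / n_sub
            for k in range(n_sub):
                tau = t[i] + (k + 0.5) * h
                s_mid = np.interp(tau, t, s)
                rate = float(transport.rate_at(remaining / transport.gel_volume_ml)) * s_mid * UG_PER_NG
                remaining -= min(rate * h, remaining)
    return pd.DataFrame(
        {"t_h": t, "S_mm2": s, "conc_ug_per_ml": conc, "PhiP_ug_per_h": phi, "cum_P_ug": cum}
    )


def daily_uptake_ug(
    total_length_um: float, mean_radius_um: float, J_ng_per_mm2_h: float
) -> float:
    """P extracted per day (ug) by a network of given length and mean radius.

    Worked-example helper: surface ``2 pi r L`` times J times 24 h.
    """
    from .morphometry import edge_surface_volume
    from ._units import MM2_PER_UM2

    surface_mm2 = edge_surface_volume(total_length_um, mean_radius_um)[0] * MM2_PER_UM2
    return J_ng_per_mm2_h * surface_mm2 * HOURS_PER_DAY * UG_PER_NG


@dataclass
class MediaPhosphorus:
    """Compartment phosphorus accounting for a growth-medium recipe."""

    total_mass_ug: float
    total_conc_ug_per_ml: float
    accessible_conc_ug_per_ml: float
    accessible_mass_ug: float


def media_phosphorus(
    volume_ml: float = 28.0,
    kh2po4_mg_per_l: float = 4.1,
    phytagel_g_per_l: float = 3.0,
    phytagel_P_umol_per_g: float = 27.0,
    inaccessible_conc_ug_per_ml: float = 2.0,
) -> MediaPhosphorus:
    """Total and accessible P in a gel compartment.

    P arrives from KH2PO4 (mass fraction from standard atomic masses) and
    from the Phytagel gelling agent (umol P per g of gel powder); the
    adsorbed inaccessible concentration is subtracted (floored at 0) to give
    what fungus and root can actually extract.
    """
    for name, value in [
        ("volume_ml", volume_ml),
        ("kh2po4_mg_per_l", kh2po4_mg_per_l),
        ("phytagel_g_per_l", phytagel_g_per_l),
        ("phytagel_P_umol_per_g", phytagel_P_umol_per_g),
        ("inaccessible_conc_ug_per_ml", inaccessible_conc_ug_per_ml),
    ]:
        if value < 0:
            raise ValueError(f"{name} must be non-negative")
    # mg/L == ug/mL; g/L == mg/mL
    conc_from_salt = kh2po4_mg_per_l * P_MASS_FRACTION_KH2PO4
    conc_from_gel = phytagel_g_per_l * 1e-3 * phytagel_P_umol_per_g * ATOMIC_MASS_P
    total_conc = conc_from_salt + conc_from_gel
    accessible_conc = max(total_conc - inaccessible_conc_ug_per_ml, 0.0)
    return MediaPhosphorus(
        total_mass_ug=total_conc * volume_ml,
        total_conc_ug_per_ml=total_conc,
        accessible_conc_ug_per_ml=accessible_conc,
        accessible_mass_ug=accessible_conc * volume_ml,
    )


def exchange_ratio_fit(
    phi_c,
    phi_p,
    through_origin: bool = True,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Exchange-rate slope of PhiC against PhiP with a bootstrap CI.

    Through-origin slope ``sum(PhiC*PhiP) / sum(PhiP^2)`` by default; the
    free-intercept variant uses ordinary least squares.
    """
    x = np.asarray(phi_p, dtype=float)
    y = np.asarray(phi_c, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) == 0:
        raise ValueError("no finite paired points")

    def slope_of(xs, ys):
        if through_origin:
            denom = float(np.sum(xs**2))
            if denom == 0:
                return np.nan
            return float(np.sum(xs * ys) / denom)
        if len(xs) < 2 or np.ptp(xs) == 0:
            return np.nan
        return float(stats.linregress(xs, ys).slope)

    slope = slope_of(x, y)
    if not np.isfinite(slope):
        raise ValueError("slope undefined (all PhiP zero or degenerate design)")
    rng = np.random.default_rng(seed)
    idx = np.arange(len(x))
    boot = np.asarray(
        [slope_of(x[(take := rng.choice(idx, len(idx)))], y[take]) for _ in range(n_boot)]
    )
    alpha = (1.0 - ci_level) / 2.0
    ci = np.nanquantile(boot, [alpha, 1.0 - alpha])
    return slope, (float(ci[0]), float(ci[1]))


def binned_average(t_h, values, bin_width_h: float = 10.0) -> pd.DataFrame:
    """Per-bin mean +/- 2 s.e.m. over non-overlapping time bins from t=0.

    Returns ``bin_left, bin_center, mean, sem, ci_lo, ci_hi, n``; empty bins
    are omitted.  ``sem = sd / sqrt(n)`` with ddof=1 (0 for singleton bins).
    """
    if bin_width_h <= 0:
        raise ValueError("bin width must be positive")
    t = np.asarray(t_h, dtype=float)
    v = np.asarray(values, dtype=float)
    bins = np.floor(t / bin_width_h).astype(int)
    rows = []
    for b in np.unique(bins):
        sel = bins == b
        vals = v[sel]
        mean = float(vals.mean())
        sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        rows.append(
            {
                "bin_left_h": b * bin_width_h,
                "bin_center_h": (b + 0.5) * bin_width_h,
                "mean": mean,
                "sem": sem,
                "ci_lo": mean - 2 * sem,
                "ci_hi": mean + 2 * sem,
                "n": int(len(vals)),
            }
        )
    return pd.DataFrame(rows)


def compute_flux_series(
    snapshots,
    carbon: CarbonParams,
    transport: TransportParams,
    P_budget_ug: float,
    smoothing_window_h: float = 10.0,
) -> pd.DataFrame:
    """End-to-end flux table for a snapshot sequence.

    Columns: ``t_h, Ct_ug, PhiC_ug_per_h, S_mm2, conc_ug_per_ml,
    PhiP_ug_per_h, kappa`` — kappa = PhiC/PhiP is left NaN where PhiP = 0.
    """
    from .morphometry import compute_series

    series = compute_series(snapshots)
    t = series["t_h"].to_numpy(float)
    ct = np.asarray([total_carbon(s, carbon) for s in snapshots])
    phi_c, _ = carbon_flux(t, ct, carbon, smoothing_window_h)
    phos = phosphorus_flux(t, series["S_mm2"].to_numpy(float), transport, P_budget_ug)
    phi_p = phos["PhiP_ug_per_h"].to_numpy(float)
    kappa = np.where(phi_p > 0, phi_c / np.where(phi_p > 0, phi_p, 1.0), np.nan)
    return pd.DataFrame(
        {
            "t_h": t,
            "Ct_ug": ct,
            "PhiC_ug_per_h": phi_c,
            "S_mm2": series["S_mm2"],
            "conc_ug_per_ml": phos["conc_ug_per_ml"],
            "PhiP_ug_per_h": phi_p,
            "kappa": kappa,
        }
    )
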