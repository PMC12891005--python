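"""Isoexchange Pareto fronts and the exploration/exploitation strategy sweep.

A fungal growth strategy is a point in (wave speed ``v_wave``, surface-area
density ``rho_S``) space.  Holding the carbon-per-phosphorus exchange rate
at ``kappa0`` bounds the achievable strategies from above: in the long-time
(depletion-front) limit the carbon density must satisfy ``rho_C = kappa0 *
CUE * [P]0 * d``, and with the speed-dependent hyphal radius ``<r> =
a*v_wave + b`` this becomes a family of "isoexchange" curves

    rho_S(v_wave) = kappa0 * CUE * [P]0 * d / (MC * pi * xi * (a*v_wave + b))

decreasing and convex in ``v_wave``: a network can explore fast (high
``v_wave``) or exploit densely (high ``rho_S``) but not both, and raising
``kappa0`` shifts the whole front up.  (The curve is stated up to a
convention-dependent constant factor; its shape, ordering and linearity in
``kappa0`` do not depend on that factor.)

Also here: the empirical front (running maximum of ``rho_S`` in order of
decreasing ``v_wave``) and the strategy sweep that reruns the wave model
over a ``v_wave x [P]0`` grid and scores each cell by total P transferred,
row-normalised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._units import MM_PER_UM, UG_PER_MM3_PER_UG_PER_ML
from .exchange_fluxes import CarbonParams
from .wave_model import default_params, run_simulation

__all__ = [
    "IsoexchangeConstants",
    "ParetoCurve",
    "isoexchange_curve",
    "empirical_front",
    "strategy_sweep",
]


@dataclass(frozen=True)
class IsoexchangeConstants:
    """Analytic constants entering the isoexchange relation."""

    cue: float = 0.5
    P0_conc_ug_per_ml: float = 1.4
    gel_depth_mm: float = 2.5
    MC_ug_per_mm3: float = CarbonParams().MC_ug_per_mm3
    xi: float = 1.25
    radius_a_um_per_um_h: float = 0.01
    radius_b_um: float = 1.5


@dataclass
class ParetoCurve:
    """One isoexchange-rate locus rho_S(v_wave) at fixed kappa0."""

    kappa0: float
    v_wave_um_per_h: np.ndarray
    rho_s: np.ndarray
    constants: IsoexchangeConstants = field(default_factory=IsoexchangeConstants)


def isoexchange_curve(
    kappa0: float,
    constants: IsoexchangeConstants | None = None,
    v_wave_grid_um_per_h=None,
) -> ParetoCurve:
    """Isoexchange curve rho_S(v_wave) at a fixed exchange rate."""
    constants = constants or IsoexchangeConstants()
    if v_wave_grid_um_per_h is None:
        v_wave_grid_um_per_h = np.linspace(50.0, 400.0, 100)
    v = np.asarray(v_wave_grid_um_per_h, dtype=float)
    mean_radius_um = constants.radius_a_um_per_um_h * v + constants.radius_b_um
    if np.any(mean_radius_um <= 0):
        raise ValueError("v_wave grid crosses the pole of the radius law (a*v+b <= 0)")
    rho_s = (
        kappa0
        * constants.cue
        * constants.P0_conc_ug_per_ml * UG_PER_MM3_PER_UG_PER_ML
        * constants.gel_depth_mm
        / (constants.MC_ug_per_mm3 * np.pi * constants.xi * mean_radius_um * MM_PER_UM)
    )
    return ParetoCurve(kappa0=float(kappa0), v_wave_um_per_h=v, rho_s=rho_s,
                       constants=constants)


def empirical_front(points: pd.DataFrame) -> pd.DataFrame:
    """Moving maximum of rho_S for decreasing v_wave.

    ``points`` needs columns ``v_wave_um_per_h`` and ``rho_s``.  Returns the
    step polyline (sorted by decreasing v_wave with the running maximum);
    no input point lies strictly above it.
    """
    if len(points) == 0:
        raise ValueError("need at least one point")
    ordered = points.sort_values("v_wave_um_per_h", ascending=False, kind="stable")
    front = ordered.copy()
    front["rho_s_front"] = np.maximum.accumulate(ordered["rho_s"].to_numpy(float))
    return front.reset_index(drop=True)


def strategy_sweep(
    v_wave_values_um_per_h,
    P0_values_ug_per_ml,
    T_h: float = 900.0,
    dish_radius_mm: float = 40.0,
    reference_P0_ug_per_ml: float = 1.4,
    kappa0: float = 3.0,
    base_params_overrides: dict | None = None,
    save_interval_h: float = 10.0,
) -> pd.DataFrame:
    """Total-P-transfer performance over a strategy x environment grid.

    A *strategy* is a point on the isoexchange Pareto front of the
    reference environment: its nominal wave speed sets the hyphal radius
    through the speed-radius law, and its branching rate is initialised so
    the colony density matches the isoexchange relation at
    ``reference_P0_ug_per_ml`` (a heritable trait, not re-optimised per
    environment).  Each cell then runs the full model — exchange-rate
    feedback included — in a closed dish of radius ``dish_radius_mm`` at
    the row's accessible concentration ``[P]0``, to horizon ``T_h``;
    ``Ptot`` is the cumulative P transferred.  Rows are normalised by
    their mean over valid cells, so each entry is the relative advantage
    of a strategy in that environment.  Failed cells are flagged NaN.

    Returns a tidy frame: ``P0_ug_per_ml, v_wave_um_per_h, Ptot_ug,
    Ptot_rel, ok``.
    """
    v_values = np.asarray(v_wave_values_um_per_h, dtype=float)
    p_values = np.asarray(P0_values_ug_per_ml, dtype=float)
    if len(v_values) == 0 or len(p_values) == 0:
        raise ValueError("sweep grid must be non-empty")
    overrides = dict(base_params_overrides or {})
    rows = []
    for p0 in p_values:
        ptots = []
        for v in v_values:
            probe = default_params(v, **overrides)
            # trait density: Eq.-8 balance in the reference environment
            mean_r2_mm3 = (
                probe.carbon.MC_ug_per_mm3 * np.pi * probe.xi
                * probe.mean_radius_um**2 * 1e-9
            )
            rho_trait = (
                kappa0 * probe.carbon.cue
                * reference_P0_ug_per_ml * UG_PER_MM3_PER_UG_PER_ML
                * probe.gel_depth_mm / mean_r2_mm3
            )
            alpha_trait = float(
                np.clip(probe.beta_mm2_per_um_h * rho_trait, 1e-4,
                        probe.alpha_max_per_h)
            )
            params = default_params(
                v,
                P0_conc_ug_per_ml=float(p0),
                Rmax_mm=dish_radius_mm,
                boundary="closed",
                alpha0_per_h=alpha_trait,
                kappa0=kappa0,
                **overrides,
            )
            try:
                result = run_simulation(params, T_h, save_interval_h=save_interval_h)
                ptots.append(float(result.saves["P_transferred_ug"].iloc[-1]))
            except Exception:
                ptots.append(np.nan)
        ptots = np.asarray(ptots)
        valid = np.isfinite(ptots)
        mean = float(np.mean(ptots[valid])) if valid.any() else np.nan
        for v, ptot in zip(v_values, ptots):
            rows.append(
                {
                    "P0_ug_per_ml": float(p0),
                    "v_wave_um_per_h": float(v),
                    "Ptot_ug": float(ptot) if np.isfinite(ptot) else np.nan,
                    "Ptot_rel": float(ptot / mean) if np.isfinite(ptot) and mean else np.nan,
                    "ok": bool(np.isfinite(ptot)),
                }
            )
    return pd.DataFrame(rows)
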