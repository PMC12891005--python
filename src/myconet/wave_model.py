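"""Extended traveling-wave model of mycorrhizal network range expansion.

Radially symmetric continuum model of a fungal colony expanding over a gel
of depth ``d`` holding phosphorus at concentration ``[P]``:

* hyphal length density ``rho(R, t)`` (um/mm^2) grows where tips elongate:
  ``d(rho)/dt = vg * n``,
* tip density ``n(R, t)`` (mm^-2) branches at rate ``alpha``, is annihilated
  by anastomosis with existing filament at rate ``beta * n * rho``, and
  moves outward through a density flux ``j(n) = c*n - D*grad(n)``
  (advection + diffusion — a minimal flux law supporting constant-speed
  fronts; the realised wave speed is always *measured* from the run, never
  assumed),
* the local P concentration is drawn down by transporter-limited uptake:
  ``d[P]/dt = -J([P]) * rhoS_local / d`` with ``rhoS_local = 2*pi*<r>*rho``
  the dimensionless surface-area density and Michaelis-Menten ``J([P])``,
* the branching rate carries a negative integral feedback acting on its
  logarithm, ``d(ln alpha)/dt = -kI * (kappa - kappa0)/kappa0``, holding
  the realised carbon-per-phosphorus exchange ratio ``kappa = PhiC/PhiP``
  at the setpoint ``kappa0`` (the multiplicative form keeps alpha positive
  and makes the loop gain scale-free),
* the mean hyphal radius follows the speed law ``<r> = a*v_wave + b``
  (faster-expanding networks invest in thicker runner hyphae), and
  ``<r^2> = xi * <r>^2`` with ``xi = 1 + CV^2`` of the radius distribution.

Carbon expenditure is ``PhiC = (MC/CUE) * d/dt int pi <r^2> rho dA +
sigma_spore * int rho dA`` (hyphal building plus a spore-production term
proportional to standing mycelium); phosphorus supply is ``PhiP = int
J([P]) rhoS dA``.

Numerics: explicit Euler, first-order upwind advection and centred
diffusion in conservative cylindrical form, reflective boundary at R=0 and
either outflow ("open") or reflective ("closed", a finite dish) at Rmax.
Branching is cut off below a tiny tip density so the front is pushed at a
speed set by the flux law rather than by the exponential leading edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._units import MM_PER_UM, MM2_PER_UM2, MM3_PER_UM3, UG_PER_NG, UM_PER_MM
from .exchange_fluxes import CarbonParams

__all__ = [
    "WaveModelParams",
    "WaveModelState",
    "SimulationResult",
    "InstabilityError",
    "default_params",
    "initial_state",
    "step",
    "run_simulation",
    "analytic_regime2_fluxes",
    "analytic_regime3_ratio",
    "depletion_width",
]

#: the front sits where rho crosses this fraction of its current maximum
FRONT_RHO_FRACTION = 0.05
#: absolute floor (um/mm^2) so an empty lattice has no front
FRONT_RHO_MIN = 1.0


class InstabilityError(RuntimeError):
    pass


@dataclass(frozen=True)
class WaveModelParams:
    """Parameters of the extended traveling-wave model (units in names)."""

    vg_um_per_h: float = 200.0            # tip elongation speed
    alpha0_per_h: float = 0.04            # initial branching rate
    beta_mm2_per_um_h: float = 8e-5       # anastomosis coefficient
    advection_mm_per_h: float = 0.15      # c in j(n) = c n - D grad n
    diffusion_mm2_per_h: float = 0.04     # D
    kI_per_h: float = 0.007               # integral feedback gain (on ln alpha)
    kappa0: float = 3.0                   # exchange-rate setpoint (mass C / mass P)
    Jmax_ng_per_mm2_h: float = 3.0
    Km_ug_per_ml: float = 0.3
    P0_conc_ug_per_ml: float = 1.4        # accessible P ahead of the front
    gel_depth_mm: float = 2.5
    radius_a_um_per_um_h: float = 0.01    # <r> = a * v_wave + b
    radius_b_um: float = 1.5
    xi: float = 1.25                      # <r^2>/<r>^2 = 1 + CV^2
    sigma_spore_ug_per_um_h: float = 5e-9
    carbon: CarbonParams = field(default_factory=CarbonParams)
    v_wave_nominal_um_per_h: float = 150.0
    # grid
    dR_mm: float = 0.25
    Rmax_mm: float = 150.0
    dt_h: float = 0.25
    boundary: str = "open"                # "open" (outflow) or "closed" (dish wall)
    # numerical guards
    alpha_max_per_h: float = 3.0
    n_cutoff_mm2: float = 1e-4            # no branching below this tip density
    tau_kappa_h: float = 6.0              # flux-ratio smoothing time constant
    phi_p_min_ug_per_h: float = 1e-6      # feedback inactive below this PhiP

    def __post_init__(self) -> None:
        for name in (
            "vg_um_per_h", "alpha0_per_h", "beta_mm2_per_um_h",
            "advection_mm_per_h", "diffusion_mm2_per_h", "kI_per_h",
            "Jmax_ng_per_mm2_h", "Km_ug_per_ml", "P0_conc_ug_per_ml",
            "gel_depth_mm", "xi", "sigma_spore_ug_per_um_h",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.dR_mm <= 0 or self.dt_h <= 0 or self.Rmax_mm <= self.dR_mm:
            raise ValueError("grid spacing, timestep and extent must be positive")
        if self.boundary not in ("open", "closed"):
            raise ValueError("boundary must be 'open' or 'closed'")
        adv_cfl = self.advection_mm_per_h * self.dt_h / self.dR_mm
        diff_cfl = 2.0 * self.diffusion_mm2_per_h * self.dt_h / self.dR_mm**2
        if adv_cfl > 1.0 or diff_cfl > 1.0:
            raise ValueError(
                f"CFL violated: advection {adv_cfl:.3f}, diffusion {diff_cfl:.3f} "
                "(both must be <= 1)"
            )

    @property
    def mean_radius_um(self) -> float:
        return self.radius_a_um_per_um_h * self.v_wave_nominal_um_per_h + self.radius_b_um

    @property
    def n_cells(self) -> int:
        return int(round(self.Rmax_mm / self.dR_mm))

    def grid_mm(self) -> np.ndarray:
        """Cell-centre radii."""
        return (np.arange(self.n_cells) + 0.5) * self.dR_mm

    def cell_areas_mm2(self) -> np.ndarray:
        """Annulus areas; they sum exactly to pi*Rmax^2."""
        faces = np.arange(self.n_cells + 1) * self.dR_mm
        return np.pi * (faces[1:] ** 2 - faces[:-1] ** 2)

    def with_(self, **overrides) -> "WaveModelParams":
        return replace(self, **overrides)


def default_params(v_wave_um_per_h: float = 150.0, **overrides) -> WaveModelParams:
    """Parameter set targeting a nominal wave speed.

    The front is pulled: its speed is approximately ``c + 2*sqrt(D_eff *
    alpha)`` where ``D_eff`` includes the upwind scheme's numerical
    diffusion ``c*dR/2*(1 - c*dt/dR)``.  The advection speed ``c`` is
    calibrated against that dispersion relation so the realised speed lands
    near the nominal target at the initial branching rate; the realised
    speed is still always measured from the run, never assumed.
    """
    probe = WaveModelParams(v_wave_nominal_um_per_h=v_wave_um_per_h, **overrides)
    target = v_wave_um_per_h * MM_PER_UM
    c = target / 2.0
    for _ in range(50):
        d_num = c * probe.dR_mm / 2.0 * max(1.0 - c * probe.dt_h / probe.dR_mm, 0.0)
        pulled = 2.0 * np.sqrt((probe.diffusion_mm2_per_h + d_num) * probe.alpha0_per_h)
        c_new = max(target - pulled, 1e-4)
        if abs(c_new - c) < 1e-10:
            c = c_new
            break
        c = 0.5 * (c + c_new)
    base = dict(
        advection_mm_per_h=c,
        v_wave_nominal_um_per_h=v_wave_um_per_h,
    )
    base.update(overrides)
    base.pop("v_wave_nominal_um_per_h", None)
    return WaveModelParams(v_wave_nominal_um_per_h=v_wave_um_per_h, **base)


@dataclass
class WaveModelState:
    """Radial fields plus the feedback and bookkeeping variables."""

    t_h: float
    rho: np.ndarray              # um/mm^2
    n: np.ndarray                # mm^-2
    P: np.ndarray                # ug/mL (accessible)
    alpha_per_h: float
    C_spent_ug: float = 0.0
    P_transferred_ug: float = 0.0
    kappa_smooth: float = np.nan
    phi_c_ug_per_h: float = 0.0
    phi_p_ug_per_h: float = 0.0
    feedback_engaged: bool = False


def initial_state(params: WaveModelParams) -> WaveModelState:
    """Gaussian tip pulse at the origin, bare substrate, uniform P."""
    r = params.grid_mm()
    n = 10.0 * np.exp(-(r**2) / (2.0 * 1.0**2))
    n[n < 1e-12] = 0.0
    return WaveModelState(
        t_h=0.0,
        rho=np.zeros_like(r),
        n=n,
        P=np.full_like(r, params.P0_conc_ug_per_ml),
        alpha_per_h=params.alpha0_per_h,
    )


def _fluxes(state: WaveModelState, params: WaveModelParams) -> tuple[float, float, np.ndarray]:
    """Instantaneous (PhiC, PhiP, P-removal-rate field) of a state.

    PhiP here is the uncapped Michaelis-Menten rate; `step` caps removal at
    the locally available P.
    """
    areas = params.cell_areas_mm2()
    r_mean = params.mean_radius_um
    r2_mean = params.xi * r_mean**2
    # carbon: building (MC/CUE * pi <r^2> * vg * total tips) + spores
    mc = params.carbon.MC_ug_per_mm3
    total_tips = float(np.sum(state.n * areas))
    total_length_um = float(np.sum(state.rho * areas))
    phi_c = (
        mc / params.carbon.cue
        * np.pi * r2_mean * MM3_PER_UM3
        * params.vg_um_per_h * total_tips
        + params.sigma_spore_ug_per_um_h * total_length_um
    )
    # phosphorus: J([P]) * rhoS per unit area, integrated
    rho_s = 2.0 * np.pi * r_mean * state.rho * MM2_PER_UM2  # dimensionless
    conc = np.maximum(state.P, 0.0)
    if params.Km_ug_per_ml == 0:
        j_areal = np.where(conc > 0, params.Jmax_ng_per_mm2_h, 0.0)
    else:
        j_areal = params.Jmax_ng_per_mm2_h * conc / (conc + params.Km_ug_per_ml)
    uptake_conc_rate = j_areal * rho_s / params.gel_depth_mm  # ng/mm^3/h == ug/mL/h
    phi_p = float(
        np.sum(uptake_conc_rate * areas * params.gel_depth_mm) * MM3_PER_ML_MASS
    )
    return phi_c, phi_p, uptake_conc_rate


#: ug of P per (ug/mL * mm^3): conc * volume / 1000
MM3_PER_ML_MASS = 1e-3


def step(state: WaveModelState, params: WaveModelParams) -> WaveModelState:
    """One explicit update; returns a new state."""
    dt = params.dt_h
    dr = params.dR_mm
    ncells = params.n_cells
    r_faces = np.arange(ncells + 1) * dr
    r_centers = params.grid_mm()
    areas = params.cell_areas_mm2()

    n = state.n
    rho = state.rho

    # --- tip transport: conservative cylindrical advection + diffusion ----
    flux = np.zeros(ncells + 1)
    # interior faces k = 1..N-1; upwind for c > 0
    flux[1:-1] = (
        params.advection_mm_per_h * n[:-1]
        - params.diffusion_mm2_per_h * (n[1:] - n[:-1]) / dr
    )
    flux[0] = 0.0  # reflective at the origin
    if params.boundary == "open":
        flux[-1] = params.advection_mm_per_h * n[-1]
    else:
        flux[-1] = 0.0
    divergence = (r_faces[1:] * flux[1:] - r_faces[:-1] * flux[:-1]) / (r_centers * dr)

    # --- branching / anastomosis (branching cut off at tiny tip density) --
    branch = np.where(n > params.n_cutoff_mm2, state.alpha_per_h * n, 0.0)
    anastomose = params.beta_mm2_per_um_h * n * rho

    n_new = n + dt * (branch - anastomose - divergence)
    n_new = np.maximum(n_new, 0.0)
    rho_new = rho + dt * params.vg_um_per_h * n

    # --- fluxes and P drawdown (removal capped at available P) ------------
    phi_c, _, uptake_rate = _fluxes(state, params)
    removed_conc = np.minimum(np.maximum(state.P, 0.0), uptake_rate * dt)
    P_new = state.P - removed_conc
    removed_mass = float(np.sum(removed_conc * areas * params.gel_depth_mm) * MM3_PER_ML_MASS)
    phi_p = removed_mass / dt

    # --- exchange-rate feedback on the branching rate ---------------------
    # The integral law engages once a fully depleted zone exists: before
    # that, kappa is structurally independent of the branching rate (it
    # cancels from PhiC/PhiP in the pure traveling-wave regime), and
    # integrating the error then only winds the controller up.
    kappa_smooth = state.kappa_smooth
    alpha_new = state.alpha_per_h
    if state.feedback_engaged:
        engaged = True
    else:
        r_front = front_position_mm(state, params)
        width = depletion_width(state, params)
        engaged = bool(r_front > 5.0 * params.dR_mm and width < 0.8 * r_front)
    if phi_p > params.phi_p_min_ug_per_h:
        kappa_inst = phi_c / phi_p
        if np.isnan(kappa_smooth):
            kappa_smooth = kappa_inst
        else:
            w = dt / params.tau_kappa_h
            kappa_smooth += w * (kappa_inst - kappa_smooth)
        if params.kI_per_h > 0 and engaged:
            log_step = -dt * params.kI_per_h * (
                (kappa_smooth - params.kappa0) / params.kappa0
            )
            alpha_new = state.alpha_per_h * float(np.exp(log_step))
            alpha_new = float(np.clip(alpha_new, 1e-6, params.alpha_max_per_h))

    for name, arr in (("rho", rho_new), ("n", n_new)):
        if np.any(np.abs(arr) > 1e12) or not np.all(np.isfinite(arr)):
            adv_cfl = params.advection_mm_per_h * dt / dr
            diff_cfl = 2 * params.diffusion_mm2_per_h * dt / dr**2
            raise InstabilityError(
                f"field {name} blew up at t={state.t_h:.1f} h "
                f"(advection CFL {adv_cfl:.3f}, diffusion CFL {diff_cfl:.3f})"
            )

    return WaveModelState(
        t_h=state.t_h + dt,
        rho=rho_new,
        n=n_new,
        P=P_new,
        alpha_per_h=alpha_new,
        C_spent_ug=state.C_spent_ug + phi_c * dt,
        P_transferred_ug=state.P_transferred_ug + removed_mass,
        kappa_smooth=kappa_smooth,
        phi_c_ug_per_h=phi_c,
        phi_p_ug_per_h=phi_p,
        feedback_engaged=engaged,
    )


def front_position_mm(state: WaveModelState, params: WaveModelParams) -> float:
    """Outermost radius where rho exceeds the colonisation threshold."""
    threshold = max(FRONT_RHO_MIN, FRONT_RHO_FRACTION * float(state.rho.max()))
    above = np.flatnonzero(state.rho > threshold)
    if len(above) == 0:
        return 0.0
    return float(params.grid_mm()[above[-1]])


def depletion_width(
    state: WaveModelState,
    params: WaveModelParams,
    threshold_fraction: float = 0.05,
    method: str = "threshold",
) -> float:
    """Width (mm) of the annulus behind the front where P is not depleted.

    ``method='threshold'``: contiguous block of cells adjacent to the front
    with ``[P] > threshold_fraction * [P]0``.  ``method='uptake'``: the
    uptake-equivalent width ``int J([P]) dR / J([P]0)`` behind the front —
    the sharp-front width that would give the same P supply at the
    fresh-substrate rate, appropriate when the Michaelis-Menten ramp makes
    the threshold width fuzzy.  While nothing is depleted (or no front
    exists yet) both definitions equal the wave radius itself.
    """
    if method not in ("threshold", "uptake"):
        raise ValueError("method must be 'threshold' or 'uptake'")
    r_front = front_position_mm(state, params)
    if r_front == 0.0:
        return 0.0
    grid = params.grid_mm()
    inside = grid <= r_front
    if method == "uptake":
        conc = np.maximum(state.P, 0.0)
        if params.Km_ug_per_ml == 0:
            j_rel = (conc > 0).astype(float)
        else:
            j0 = params.P0_conc_ug_per_ml / (params.P0_conc_ug_per_ml + params.Km_ug_per_ml)
            j_rel = conc / (conc + params.Km_ug_per_ml) / j0
        return float(np.sum(j_rel[inside]) * params.dR_mm)
    not_depleted = state.P > threshold_fraction * params.P0_conc_ug_per_ml
    blocked = inside & ~not_depleted
    if not blocked.any():
        return r_front
    inner_edge = grid[np.flatnonzero(blocked)[-1]]  # innermost fresh cell boundary
    return float(max(r_front - inner_edge, 0.0))


@dataclass
class SimulationResult:
    """Trajectory of a model run.

    ``saves`` has one row per save interval: ``t_h, R_front_mm, dR_mm,
    PhiC_ug_per_h, PhiP_ug_per_h, kappa, alpha_per_h, C_spent_ug,
    P_transferred_ug``.  ``fields`` optionally stores the radial profiles
    at each save.  ``v_wave_um_per_h`` is the realised front speed fitted
    over the second half of the run; ``t0_h``/``t1_h`` are the detected
    regime boundaries (front established / depletion front co-moving),
    NaN when not reached.
    """

    params: WaveModelParams
    saves: pd.DataFrame
    grid_mm: np.ndarray
    fields: dict
    v_wave_um_per_h: float
    v_wave_r_squared: float
    t0_h: float
    t1_h: float

    @property
    def final_state(self) -> WaveModelState:
        return self._final_state

    _final_state: WaveModelState = None


def run_simulation(
    params: WaveModelParams,
    T_h: float,
    save_interval_h: float = 2.0,
    store_fields: bool = False,
) -> SimulationResult:
    """Integrate the model to ``T_h`` and assemble the trajectory."""
    if T_h <= 0:
        raise ValueError("T must be positive")
    state = initial_state(params)
    n_steps = int(round(T_h / params.dt_h))
    save_every = max(1, int(round(save_interval_h / params.dt_h)))

    rows = []
    fields = {"rho": [], "n": [], "P": []} if store_fields else {}

    def record(s: WaveModelState) -> None:
        r_front = front_position_mm(s, params)
        rows.append(
            {
                "t_h": s.t_h,
                "R_front_mm": r_front,
                "dR_mm": depletion_width(s, params),
                "PhiC_ug_per_h": s.phi_c_ug_per_h,
                "PhiP_ug_per_h": s.phi_p_ug_per_h,
                "kappa": (s.phi_c_ug_per_h / s.phi_p_ug_per_h
                          if s.phi_p_ug_per_h > 0 else np.nan),
                "alpha_per_h": s.alpha_per_h,
                "C_spent_ug": s.C_spent_ug,
                "P_transferred_ug": s.P_transferred_ug,
            }
        )
        if store_fields:
            fields["rho"].append(s.rho.copy())
            fields["n"].append(s.n.copy())
            fields["P"].append(s.P.copy())

    record(state)
    for k in range(1, n_steps + 1):
        state = step(state, params)
        if k % save_every == 0 or k == n_steps:
            record(state)

    saves = pd.DataFrame(rows)
    v_wave, v_r2 = _fit_front_speed(saves)
    t0 = _detect_t0(saves, v_wave)
    t1 = _detect_t1(saves)
    result = SimulationResult(
        params=params,
        saves=saves,
        grid_mm=params.grid_mm(),
        fields={k: np.asarray(v) for k, v in fields.items()},
        v_wave_um_per_h=v_wave,
        v_wave_r_squared=v_r2,
        t0_h=t0,
        t1_h=t1,
    )
    result._final_state = state
    return result


def _fit_front_speed(saves: pd.DataFrame) -> tuple[float, float]:
    t = saves["t_h"].to_numpy(float)
    r = saves["R_front_mm"].to_numpy(float)
    late = t >= t.max() / 2.0
    if late.sum() < 3 or np.ptp(t[late]) == 0:
        return np.nan, np.nan
    fit = stats.linregress(t[late], r[late])
    r2 = float(fit.rvalue**2) if np.isfinite(fit.rvalue) else 0.0
    return float(fit.slope * UM_PER_MM), r2


def _detect_t0(saves: pd.DataFrame, v_wave_um_per_h: float) -> float:
    """First time from which the front moves at the asymptotic speed.

    Earliest save after which the instantaneous front speed stays within
    25% of the late-time fit.
    """
    if not np.isfinite(v_wave_um_per_h) or v_wave_um_per_h <= 0:
        return np.nan
    t = saves["t_h"].to_numpy(float)
    r = saves["R_front_mm"].to_numpy(float)
    if len(t) < 5:
        return np.nan
    # smooth over ~20 h: the front position is quantised to the radial grid
    dt = np.median(np.diff(t))
    width = max(1, int(round(20.0 / dt)))
    kernel = np.ones(width) / width
    r_smooth = np.convolve(np.pad(r, width // 2, mode="edge"), kernel,
                           mode="same")[width // 2:width // 2 + len(r)]
    speed = np.gradient(r_smooth, t) * UM_PER_MM
    ok = np.abs(speed - v_wave_um_per_h) <= 0.25 * v_wave_um_per_h
    # trailing run of True
    idx = len(ok)
    for i in range(len(ok) - 1, -1, -1):
        if not ok[i]:
            break
        idx = i
    return float(t[idx]) if idx < len(ok) else float(t[0])


def _detect_t1(saves: pd.DataFrame, rel_tol: float = 0.05, hold_h: float = 50.0) -> float:
    """First time the depletion-annulus width detaches and stabilises.

    Requires dR < 0.95 * R_front (a depleted core exists) and dR constant
    to ``rel_tol`` over the following ``hold_h`` hours.
    """
    t = saves["t_h"].to_numpy(float)
    dr = saves["dR_mm"].to_numpy(float)
    rf = saves["R_front_mm"].to_numpy(float)
    detached = (rf > 0) & (dr < 0.95 * rf)
    for i in np.flatnonzero(detached):
        sel = (t >= t[i]) & (t <= t[i] + hold_h)
        if sel.sum() < 3:
            continue
        window = dr[sel]
        if window.mean() > 0 and np.ptp(window) <= rel_tol * window.mean():
            return float(t[i])
    return np.nan


# ---------------------------------------------------------------------------
# Analytic regime formulas (cross-checks for the simulation)
# ---------------------------------------------------------------------------

def analytic_regime2_fluxes(
    rho_c_ug_per_mm2: float,
    v_wave_um_per_h: float,
    r_wave_mm: float,
    spore_term_ug_per_h: float,
    J_ng_per_mm2_h: float,
    rho_s: float,
    delta_r_mm: float,
    cue: float,
) -> tuple[float, float]:
    """Traveling-wave fluxes while the depletion annulus spans the colony.

    ``PhiC = 2 pi (rho_C/CUE) v_wave R_wave + PhiC_spores`` and
    ``PhiP = J * 2 pi rho_S * R_wave * dR`` (all converted to ug/h).
    """
    for name, value in [
        ("rho_c", rho_c_ug_per_mm2), ("v_wave", v_wave_um_per_h),
        ("r_wave", r_wave_mm), ("spore_term", spore_term_ug_per_h),
        ("J", J_ng_per_mm2_h), ("rho_s", rho_s), ("delta_r", delta_r_mm),
    ]:
        if value < 0:
            raise ValueError(f"{name} must be non-negative")
    phi_c = (
        2.0 * np.pi * (rho_c_ug_per_mm2 / cue)
        * v_wave_um_per_h * MM_PER_UM * r_wave_mm
        + spore_term_ug_per_h
    )
    phi_p = (
        J_ng_per_mm2_h * UG_PER_NG * 2.0 * np.pi * rho_s * r_wave_mm * delta_r_mm
    )
    return float(phi_c), float(phi_p)


def analytic_regime3_ratio(
    rho_c_ug_per_mm2: float,
    cue: float,
    P0_conc_ug_per_ml: float,
    gel_depth_mm: float,
) -> float:
    """Long-time exchange ratio ``kappa = rho_C / (CUE * [P]0 * d)``.

    Once the depletion front co-moves with the growth front, the P swept per
    unit new area is the full column ``[P]0 * d``, while the carbon built
    per unit new area is ``rho_C / CUE`` — their ratio is speed-independent.
    """
    denom = cue * P0_conc_ug_per_ml * 1e-3 * gel_depth_mm  # ug/mL -> ug/mm^3
    if denom == 0:
        raise ValueError("CUE, [P]0 and gel depth must all be positive")
    return float(rho_c_ug_per_mm2 / denom)
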