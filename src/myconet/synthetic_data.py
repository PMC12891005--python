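"""Synthetic study data with known ground truth.

Generates the three kinds of input the analysis pipeline consumes, with the
statistical structure the downstream estimators assume:

* **network timelapses** — the colony expands as a traveling wave: a disk of
  radius ``R(t) = R0 + v_wave * t`` filled at constant hyphal length density
  ``rho_target``.  Edges are realised as radial "wedge" populations (per-edge
  length/radius with approximate planar placement), which is sufficient for
  every downstream statistic: the morphometry uses only per-edge ``(r, L)``
  and the hull of node positions.  Hyphal radii follow a two-component
  lognormal mixture (thin BAS-like mode, thick runner mode); runner hyphae
  widen linearly with age.  Spores accumulate behind the front.

* **phosphorus depletion assays** — per-replicate masses in the fungal
  compartment (``Pf``), the gel of the root compartment (``Pg``) and the
  host root (``Pr``): ``Pf`` decreases linearly in the time-integrated
  network surface area with slope ``-J`` (surface-limited uptake), ``Pg``
  stays at baseline, and ``Pr`` receives what ``Pf`` loses (mass closure),
  all with additive Gaussian noise.

* **transect datasets** — 120-sample intensity line profiles across a hypha,
  from a cylinder-projection model: Beer–Lambert attenuation of the chord
  depth ``2*sqrt(r^2 - x^2)``, defocus-dependent Gaussian blur, multiplicative
  illumination variation, additive noise, plus zero-radius "empty" profiles.

Everything is driven by a single integer seed: identical configurations give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from ._units import MM_PER_UM, UG_PER_NG
from .morphometry import (
    EDGE_COLUMNS,
    NODE_COLUMNS,
    SPORE_COLUMNS,
    NetworkSnapshot,
    edge_surface_volume,
    spore_volume,
)
from ._units import MM2_PER_UM2, MM3_PER_UM3

__all__ = [
    "RadiusMixtureComponent",
    "SyntheticRunConfig",
    "SyntheticTimelapse",
    "generate_timelapse",
    "generate_depletion_assay",
    "generate_transect_dataset",
    "cylinder_transect_profile",
    "TRANSECT_LENGTH",
]

TRANSECT_LENGTH = 120
#: pixel index at which generated hyphae are centred (a pixel centre, so an
#: r-um hypha attenuates exactly ceil(2r/pixel) pixels when unblurred)
TRANSECT_CENTER_PX = 60


@dataclass(frozen=True)
class RadiusMixtureComponent:
    """One lognormal mode of the hyphal radius distribution."""

    name: str
    median_um: float
    sigma_log: float
    weight: float
    widens: bool = False   # runner hyphae thicken with age; BAS do not


def _default_radius_mixture() -> tuple[RadiusMixtureComponent, ...]:
    # Thin BAS-like mode ~1.5 um and thick runner mode ~3 um at emergence
    # (runners then widen with age); together they span ~1-7 um.
    return (
        RadiusMixtureComponent("BAS", median_um=1.5, sigma_log=0.20, weight=0.5),
        RadiusMixtureComponent("RH", median_um=3.0, sigma_log=0.15, weight=0.5, widens=True),
    )


@dataclass(frozen=True)
class SyntheticRunConfig:
    """Ground-truth parameters of a synthetic study run.

    Defaults mirror the study conditions: 2-h imaging cadence over the
    <200 h steady-state traveling-wave window, wave speed 150 um/h, runner
    widening 0.015 um/h (3 -> 4.5 um over 100 h), high-P compartment of
    28 mL holding 96 ug P.
    """

    seed: int = 0
    n_replicates: int = 3
    sampling_interval_h: float = 2.0
    duration_h: float = 200.0
    v_wave_um_per_h: float = 150.0
    rho_target_um_per_mm2: float = 300.0
    radius_mixture: tuple[RadiusMixtureComponent, ...] = field(
        default_factory=_default_radius_mixture
    )
    widening_rate_um_per_h: float = 0.015
    spore_rate_per_mm2_per_h: float = 5e-5
    assay_noise_sd_ug: float = 0.5
    transect_noise_sd: float = 0.03
    pixel_size_um: float = 2.0
    P0_mass_ug: float = 96.0
    gel_volume_ml: float = 28.0
    # realisation details
    initial_radius_mm: float = 0.3
    mean_edge_length_um: float = 150.0
    edge_length_sigma_log: float = 0.35
    spore_radius_median_um: float = 25.0
    spore_radius_sigma_log: float = 0.2
    Pg_baseline_ug: float = 50.0

    def __post_init__(self) -> None:
        if self.duration_h <= 0 or self.sampling_interval_h <= 0:
            raise ValueError("duration and sampling interval must be positive")
        if self.sampling_interval_h > self.duration_h:
            raise ValueError("sampling interval exceeds duration")
        for name in (
            "v_wave_um_per_h",
            "rho_target_um_per_mm2",
            "widening_rate_um_per_h",
            "spore_rate_per_mm2_per_h",
            "assay_noise_sd_ug",
            "transect_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.pixel_size_um <= 0 or self.gel_volume_ml <= 0:
            raise ValueError("pixel size and gel volume must be positive")
        weights = sum(c.weight for c in self.radius_mixture)
        if not self.radius_mixture or weights <= 0:
            raise ValueError("radius mixture needs at least one positively weighted mode")
        medians = [c.median_um for c in self.radius_mixture]
        if min(medians) <= 0:
            raise ValueError("radius mixture medians must be positive")
        # the mixture must be able to produce the observed ~1-7 um span
        if not (min(medians) < 3.0 and max(medians) > 2.0):
            raise ValueError(
                "radius mixture should contain a thin (<3 um) and a thick (>2 um) mode"
            )

    def with_(self, **overrides) -> "SyntheticRunConfig":
        return replace(self, **overrides)


@dataclass
class SyntheticTimelapse:
    """Snapshots plus the generator's ground truth.

    ``truth`` has one row per timestep: ``t_h, R_front_mm, L_um, S_mm2,
    V_mm3, n_spores``; totals are exact sums over the realised elements.
    """

    config: SyntheticRunConfig
    snapshots: list[NetworkSnapshot]
    truth: pd.DataFrame


# ---------------------------------------------------------------------------
# Timelapse
# ---------------------------------------------------------------------------

def _sample_radius_classes(rng, mixture, n):
    weights = np.asarray([c.weight for c in mixture], dtype=float)
    weights = weights / weights.sum()
    return rng.choice(len(mixture), size=n, p=weights)


def generate_timelapse(config: SyntheticRunConfig) -> SyntheticTimelapse:
    """Realise a traveling-wave network timelapse.

    Each sampling interval adds an annulus of new edges so that hyphal
    length density behind the front stays at ``rho_target``; runner-class
    edges widen at ``widening_rate`` after their birth; spores appear behind
    the front as a Poisson process in space-time.
    """
    rng = np.random.default_rng(config.seed)
    times = np.arange(
        config.sampling_interval_h,
        config.duration_h + 1e-9,
        config.sampling_interval_h,
    )
    mixture = config.radius_mixture

    # master edge table, accumulated front-to-back
    births, classes, base_radii, lengths = [], [], [], []
    p1s, p2s = [], []
    spore_rows = []

    r_prev = 0.0
    for t in times:
        r_front = config.initial_radius_mm + config.v_wave_um_per_h * t * MM_PER_UM
        new_area = np.pi * (r_front**2 - r_prev**2)
        target_length = config.rho_target_um_per_mm2 * new_area
        n_new = max(1, int(round(target_length / config.mean_edge_length_um)))
        raw = rng.lognormal(
            np.log(config.mean_edge_length_um), config.edge_length_sigma_log, n_new
        )
        new_lengths = raw * (target_length / raw.sum())  # density exactly on target
        cls = _sample_radius_classes(rng, mixture, n_new)
        base = np.empty(n_new)
        for ci, comp in enumerate(mixture):
            sel = cls == ci
            base[sel] = rng.lognormal(np.log(comp.median_um), comp.sigma_log, sel.sum())

        # approximate planar placement: inner endpoint in the new annulus,
        # outward-pointing with angular jitter, clipped to the front
        theta = rng.uniform(0, 2 * np.pi, n_new)
        u = rng.uniform(r_prev, r_front, n_new) if r_front > r_prev else np.full(n_new, r_front)
        len_mm = new_lengths * MM_PER_UM
        u = np.minimum(u, np.maximum(r_front - len_mm, 0.0))
        direction = theta + rng.normal(0.0, 0.3, n_new)
        p1 = np.column_stack([u * np.cos(theta), u * np.sin(theta)])
        p2 = p1 + np.column_stack([len_mm * np.cos(direction), len_mm * np.sin(direction)])
        radial = np.linalg.norm(p2, axis=1)
        over = radial > r_front
        if over.any():  # fold endpoints that overshoot the front back onto it
            p2[over] *= (r_front / radial[over])[:, None]

        births.append(np.full(n_new, t))
        classes.append(cls)
        base_radii.append(base)
        lengths.append(new_lengths)
        p1s.append(p1)
        p2s.append(p2)

        if config.spore_rate_per_mm2_per_h > 0 and r_prev > 0:
            lam = config.spore_rate_per_mm2_per_h * np.pi * r_prev**2 * config.sampling_interval_h
            n_spores = rng.poisson(lam)
            if n_spores:
                ang = rng.uniform(0, 2 * np.pi, n_spores)
                rad = r_prev * np.sqrt(rng.uniform(0, 1, n_spores))
                s_radii = rng.lognormal(
                    np.log(config.spore_radius_median_um),
                    config.spore_radius_sigma_log,
                    n_spores,
                )
                for a, rr, sr in zip(ang, rad, s_radii):
                    spore_rows.append(
                        {"t_h": t, "x_mm": rr * np.cos(a), "y_mm": rr * np.sin(a),
                         "radius_um": sr}
                    )
        r_prev = r_front

    births = np.concatenate(births)
    classes = np.concatenate(classes)
    base_radii = np.concatenate(base_radii)
    lengths = np.concatenate(lengths)
    p1 = np.vstack(p1s)
    p2 = np.vstack(p2s)
    widens = np.asarray([mixture[c].widens for c in classes])
    class_names = np.asarray([mixture[c].name for c in classes])
    spores_all = pd.DataFrame(spore_rows, columns=["t_h", *SPORE_COLUMNS])

    snapshots, truth_rows = [], []
    for t in times:
        alive = births <= t + 1e-9
        idx = np.flatnonzero(alive)
        age = t - births[idx]
        radii = base_radii[idx] + np.where(
            widens[idx], config.widening_rate_um_per_h * age, 0.0
        )
        n_e = len(idx)
        nodes = pd.DataFrame(
            {
                "node_id": np.arange(2 * n_e),
                "x_mm": np.concatenate([p1[idx, 0], p2[idx, 0]]),
                "y_mm": np.concatenate([p1[idx, 1], p2[idx, 1]]),
            },
            columns=NODE_COLUMNS,
        )
        edges = pd.DataFrame(
            {
                "source": np.arange(n_e),
                "target": np.arange(n_e, 2 * n_e),
                "length_um": lengths[idx],
                "radius_um": radii,
                "hypha_class": class_names[idx],
                "birth_h": births[idx],
            }
        )
        spores = (
            spores_all.loc[spores_all["t_h"] <= t + 1e-9, SPORE_COLUMNS].reset_index(drop=True)
            if len(spores_all)
            else pd.DataFrame(columns=SPORE_COLUMNS)
        )
        snapshots.append(NetworkSnapshot(time_h=float(t), nodes=nodes, edges=edges, spores=spores))

        surf, vol = edge_surface_volume(lengths[idx], radii)
        v_spores = float(spore_volume(spores["radius_um"].to_numpy(float)).sum()) if len(spores) else 0.0
        truth_rows.append(
            {
                "t_h": float(t),
                "R_front_mm": config.initial_radius_mm + config.v_wave_um_per_h * t * MM_PER_UM,
                "L_um": float(lengths[idx].sum()),
                "S_mm2": float(surf.sum()) * MM2_PER_UM2,
                "V_mm3": (float(vol.sum()) + v_spores) * MM3_PER_UM3,
                "n_spores": len(spores),
            }
        )

    return SyntheticTimelapse(config=config, snapshots=snapshots, truth=pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# Phosphorus depletion assay
# ---------------------------------------------------------------------------

def generate_depletion_assay(
    config: SyntheticRunConfig,
    J_true_ng_per_mm2_h: float,
    harvest_times_h,
    timelapse: SyntheticTimelapse | None = None,
) -> pd.DataFrame:
    """Per-replicate (Pf, Pg, Pr) masses at the given harvest times.

    ``Pf(tm) = Pf(0) - J * integral_0^tm S dt`` (+ noise), ``Pg`` constant at
    baseline, ``Pr`` receives the transferred mass so that Pf+Pg+Pr is
    conserved at zero noise.  Surface areas come from the generated
    timelapse (pass one in to avoid regenerating).

    Returns a table with columns
    ``replicate_id, t_m_h, Pf_ug, Pg_ug, Pr_ug, intS_mm2h, depleted``.
    """
    if J_true_ng_per_mm2_h < 0:
        raise ValueError("J_true must be non-negative")
    harvest_times = np.asarray(harvest_times_h, dtype=float)
    if np.any(harvest_times < 0) or np.any(harvest_times > config.duration_h):
        raise ValueError("harvest times must lie within the run duration")

    if timelapse is None:
        timelapse = generate_timelapse(config)
    truth = timelapse.truth
    t = np.concatenate([[0.0], truth["t_h"].to_numpy(float)])
    s = np.concatenate([[0.0], truth["S_mm2"].to_numpy(float)])
    cum = np.concatenate([[0.0], np.cumsum(np.diff(t) * (s[1:] + s[:-1]) / 2.0)])
    int_s = np.interp(harvest_times, t, cum)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED_A55A]))
    rows = []
    for rep in range(config.n_replicates):
        noise = (
            rng.normal(0.0, config.assay_noise_sd_ug, size=(3, len(harvest_times)))
            if config.assay_noise_sd_ug > 0
            else np.zeros((3, len(harvest_times)))
        )
        transferred = J_true_ng_per_mm2_h * UG_PER_NG * int_s
        pf_clean = config.P0_mass_ug - transferred
        depleted = pf_clean < 0
        pf_clean = np.maximum(pf_clean, 0.0)
        pr_clean = np.minimum(transferred, config.P0_mass_ug)
        pf = np.maximum(pf_clean + noise[0], 0.0)
        pg = config.Pg_baseline_ug + noise[1]
        pr = np.maximum(pr_clean + noise[2], 0.0)
        for j, tm in enumerate(harvest_times):
            rows.append(
                {
                    "replicate_id": rep,
                    "t_m_h": float(tm),
                    "Pf_ug": float(pf[j]),
                    "Pg_ug": float(pg[j]),
                    "Pr_ug": float(pr[j]),
                    "intS_mm2h": float(int_s[j]),
                    "depleted": bool(depleted[j]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Transect dataset
# ---------------------------------------------------------------------------

#: Beer-Lambert attenuation per um of traversed cytoplasm
ATTENUATION_PER_UM = 0.12
#: in-plane blur per mm of defocus
BLUR_UM_PER_MM_DEFOCUS = 25.0


def cylinder_transect_profile(
    radius_um: float,
    pixel_size_um: float,
    defocus_mm: float = 0.0,
    illumination: float = 1.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One 120-sample intensity profile across a cylindrical hypha.

    The hypha is centred on pixel ``TRANSECT_CENTER_PX``; transmitted
    intensity is ``illumination * exp(-mu * chord(x))`` with chord depth
    ``2*sqrt(r^2 - x^2)``, optionally blurred (defocus) and noised.
    A zero radius gives a flat background profile.
    """
    half_width = TRANSECT_LENGTH / 2 * pixel_size_um
    if radius_um >= half_width:
        raise ValueError(
            f"radius {radius_um} um exceeds half the transect width {half_width} um"
        )
    x = (np.arange(TRANSECT_LENGTH) - TRANSECT_CENTER_PX) * pixel_size_um
    chord = np.zeros(TRANSECT_LENGTH)
    if radius_um > 0:
        inside = np.abs(x) < radius_um
        chord[inside] = 2.0 * np.sqrt(radius_um**2 - x[inside] ** 2)
    profile = np.exp(-ATTENUATION_PER_UM * chord)
    if defocus_mm != 0.0:
        sigma_px = BLUR_UM_PER_MM_DEFOCUS * abs(defocus_mm) / pixel_size_um
        profile = gaussian_filter1d(profile, sigma_px, mode="nearest")
    profile = illumination * profile
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        profile = profile + rng.normal(0.0, noise_sd, TRANSECT_LENGTH)
    return profile


PROFILE_COLUMNS = [f"p{i:03d}" for i in range(TRANSECT_LENGTH)]


def generate_transect_dataset(
    config: SyntheticRunConfig,
    n_samples: int,
    label_range_um: tuple[float, float] = (0.3, 8.0),
    empty_fraction: float = 0.1,
    label_noise_sd_um: float = 0.3,
    augment_defocus: bool = True,
    illumination_jitter: float = 0.2,
    n_sources: int = 40,
) -> pd.DataFrame:
    """Labelled transect table emulating the manual radius-label dataset.

    Labels span ``label_range_um`` plus a fraction of zero-radius empty
    transects; stored labels carry the manual-measurement noise
    (``label_noise_sd_um``, SD of repeated manual estimates).  Samples are
    grouped into ``n_sources`` acquisition sources for group-aware
    train/test splitting.

    Columns: ``p000..p119, label_um, true_radius_um, defocus_mm,
    illumination, source_id``.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7A3C_0FFE]))
    lo, hi = label_range_um
    is_empty = rng.uniform(size=n_samples) < empty_fraction
    radii = np.where(is_empty, 0.0, rng.uniform(lo, hi, n_samples))
    defocus = np.zeros(n_samples)
    if augment_defocus:
        blurred = rng.uniform(size=n_samples) < 0.5
        defocus = np.where(
            blurred,
            rng.choice([-1.0, 1.0], n_samples) * rng.uniform(0.1, 0.2, n_samples),
            0.0,
        )
    illumination = 1.0 + (
        rng.uniform(-illumination_jitter, illumination_jitter, n_samples)
        if illumination_jitter > 0
        else np.zeros(n_samples)
    )
    source_id = rng.integers(0, n_sources, n_samples)
    labels = radii.copy()
    if label_noise_sd_um > 0:
        labels = np.where(
            is_empty, 0.0, np.maximum(radii + rng.normal(0.0, label_noise_sd_um, n_samples), 0.0)
        )
    profiles = np.empty((n_samples, TRANSECT_LENGTH))
    for i in range(n_samples):
        profiles[i] = cylinder_transect_profile(
            radii[i],
            config.pixel_size_um,
            defocus_mm=defocus[i],
            illumination=illumination[i],
            noise_sd=config.transect_noise_sd,
            rng=rng,
        )
    out = pd.DataFrame(profiles, columns=PROFILE_COLUMNS)
    out["label_um"] = labels
    out["true_radius_um"] = radii
    out["defocus_mm"] = defocus
    out["illumination"] = illumination
    out["source_id"] = source_id
    return out
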