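"""Network-level morphometry of mycorrhizal network snapshots.

A fungal network at one timepoint is a planar spatial graph: edges are
near-cylindrical hyphal segments with a length and a radius, plus spherical
spores.  From these, this module computes the observables that drive the
carbon/phosphorus flux analysis:

* totals — hyphal length ``L``, membrane surface area ``S = sum 2*pi*r_i*L_i``
  and cell volume ``V = sum pi*r_i^2*L_i`` (+ spore spheres ``4/3*pi*r_k^3``),
* the convex-hull area ``A`` of the colonised region and the equivalent wave
  radius ``R_wave = sqrt(A/pi)``,
* densities ``rho = L/A`` (um/mm^2) and the dimensionless surface-area
  density ``rho_S = S/A``,
* the range-expansion (traveling-wave) speed ``v_wave`` from a linear fit of
  ``R_wave`` against time,
* count- and volume-weighted radius distributions.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull, QhullError

from ._units import MM2_PER_UM2, MM3_PER_UM3, UM_PER_MM

__all__ = [
    "NetworkSnapshot",
    "DegenerateGeometryError",
    "RadiusDistribution",
    "edge_surface_volume",
    "spore_volume",
    "network_totals",
    "convex_hull_metrics",
    "compute_series",
    "wave_speed",
    "radius_distribution",
    "write_snapshot_csv",
    "read_snapshot_csv",
    "write_timelapse_csv",
    "read_timelapse_csv",
    "snapshot_to_graph",
]

NODE_COLUMNS = ["node_id", "x_mm", "y_mm"]
EDGE_COLUMNS = ["source", "target", "length_um", "radius_um"]
SPORE_COLUMNS = ["x_mm", "y_mm", "radius_um"]


class DegenerateGeometryError(ValueError):
    """Raised when a snapshot has too few / collinear nodes for a hull.

    Carries ``area = 0.0`` so callers that want to continue can flag the
    timestep instead of aborting.
    """

    def __init__(self, message: str):
        super().__init__(message)
        self.area = 0.0


@dataclass
class NetworkSnapshot:
    """Spatial graph of the extraradical mycelium at one timepoint.

    Parameters
    ----------
    time_h:
        Hours since the network entered the observation compartment.
    nodes:
        DataFrame with columns ``node_id, x_mm, y_mm``.
    edges:
        DataFrame with columns ``source, target, length_um, radius_um``
        (extra columns such as a hyphal class are preserved).
    spores:
        DataFrame with columns ``x_mm, y_mm, radius_um``; may be empty.
    """

    time_h: float
    nodes: pd.DataFrame
    edges: pd.DataFrame
    spores: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=SPORE_COLUMNS))

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise ValueError(f"snapshot time must be non-negative, got {self.time_h}")
        for col in NODE_COLUMNS:
            if col not in self.nodes.columns:
                raise ValueError(f"nodes table missing column {col!r}")
        for col in EDGE_COLUMNS:
            if col not in self.edges.columns:
                raise ValueError(f"edges table missing column {col!r}")
        coords = self.nodes[["x_mm", "y_mm"]].to_numpy(float)
        if coords.size and not np.all(np.isfinite(coords)):
            raise ValueError("node coordinates must be finite")
        if len(self.edges):
            lengths = self.edges["length_um"].to_numpy(float)
            radii = self.edges["radius_um"].to_numpy(float)
            if np.any(lengths <= 0) or np.any(radii <= 0):
                raise ValueError("edge lengths and radii must be strictly positive")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def node_coords_mm(self) -> np.ndarray:
        return self.nodes[["x_mm", "y_mm"]].to_numpy(float)


def _require_positive(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be strictly positive and finite")


def edge_surface_volume(length_um, radius_um):
    """Cylinder surface area (um^2) and volume (um^3) of a hyphal edge.

    ``S_i = 2 pi r_i L_i`` and ``V_i = pi r_i^2 L_i``; accepts scalars or
    arrays (vectorized).
    """
    _require_positive("length", length_um)
    _require_positive("radius", radius_um)
    length = np.asarray(length_um, dtype=float)
    radius = np.asarray(radius_um, dtype=float)
    surface = 2.0 * np.pi * radius * length
    volume = np.pi * radius**2 * length
    if np.isscalar(length_um) and np.isscalar(radius_um):
        return float(surface), float(volume)
    return surface, volume


def spore_volume(radius_um):
    """Sphere volume (um^3) of a spore: ``V_k = 4/3 pi r_k^3``."""
    _require_positive("radius", radius_um)
    radius = np.asarray(radius_um, dtype=float)
    volume = 4.0 / 3.0 * np.pi * radius**3
    return float(volume) if np.isscalar(radius_um) else volume


def network_totals(snapshot: NetworkSnapshot) -> dict:
    """Total length (um), surface (mm^2) and volume (mm^3) of a snapshot.

    Volume includes spores; surface is hyphal membrane only.
    """
    if snapshot.n_edges == 0:
        L = S_um2 = V_um3 = 0.0
    else:
        lengths = snapshot.edges["length_um"].to_numpy(float)
        radii = snapshot.edges["radius_um"].to_numpy(float)
        surf, vol = edge_surface_volume(lengths, radii)
        L = float(lengths.sum())
        S_um2 = float(surf.sum())
        V_um3 = float(vol.sum())
    if len(snapshot.spores):
        V_um3 += float(spore_volume(snapshot.spores["radius_um"].to_numpy(float)).sum())
    return {
        "L_um": L,
        "S_mm2": S_um2 * MM2_PER_UM2,
        "V_mm3": V_um3 * MM3_PER_UM3,
    }


def convex_hull_metrics(snapshot: NetworkSnapshot) -> tuple[float, float]:
    """Convex-hull area ``A`` (mm^2) and wave radius ``R_wave = sqrt(A/pi)``.

    The hull is taken over node coordinates only (edges treated as chords).

    Raises
    ------
    DegenerateGeometryError
        If fewer than 3 nodes, or all nodes collinear.
    """
    coords = snapshot.node_coords_mm
    coords = np.unique(coords, axis=0) if coords.size else coords
    if len(coords) < 3:
        raise DegenerateGeometryError(
            f"convex hull needs >= 3 distinct nodes, got {len(coords)}"
        )
    try:
        hull = ConvexHull(coords)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate node geometry: {exc}") from exc
    area = float(hull.volume)  # 2-D: .volume is the polygon area
    return area, float(np.sqrt(area / np.pi))


def compute_series(snapshots) -> pd.DataFrame:
    """Per-timestep morphometry table for a snapshot sequence.

    Columns: ``t_h, L_um, S_mm2, V_mm3, A_mm2, R_wave_mm, rho_um_per_mm2,
    rho_S, n_spores``.  Degenerate-geometry timesteps get ``A = 0`` and are
    flagged via ``hull_ok = False``.
    """
    rows = []
    for snap in snapshots:
        totals = network_totals(snap)
        try:
            area, r_wave = convex_hull_metrics(snap)
            hull_ok = True
        except DegenerateGeometryError:
            area, r_wave, hull_ok = 0.0, 0.0, False
        rho = totals["L_um"] / area if area > 0 else np.nan
        rho_s = totals["S_mm2"] / area if area > 0 else np.nan
        rows.append(
            {
                "t_h": snap.time_h,
                **totals,
                "A_mm2": area,
                "R_wave_mm": r_wave,
                "rho_um_per_mm2": rho,
                "rho_S": rho_s,
                "n_spores": len(snap.spores),
                "hull_ok": hull_ok,
            }
        )
    return pd.DataFrame(rows).sort_values("t_h").reset_index(drop=True)


def wave_speed(series: pd.DataFrame, window_h: float | None = None) -> tuple[float, dict]:
    """Range-expansion speed (um/h) from an OLS fit of ``R_wave`` vs time.

    Parameters
    ----------
    series:
        Morphometry table from :func:`compute_series`.
    window_h:
        If given, only the trailing ``window_h`` hours are fitted (the
        traveling-wave regime is a late-time property).

    Returns
    -------
    (v_wave_um_per_h, diagnostics) where diagnostics carries the slope,
    intercept, ``r_squared`` and point count of the fit.
    """
    t = series["t_h"].to_numpy(float)
    r = series["R_wave_mm"].to_numpy(float)
    if window_h is not None:
        keep = t >= t.max() - window_h
        t, r = t[keep], r[keep]
    if len(t) < 3:
        raise ValueError(f"wave-speed fit needs >= 3 timesteps, got {len(t)}")
    fit = stats.linregress(t, r)
    v_um_per_h = fit.slope * UM_PER_MM
    diagnostics = {
        "slope_mm_per_h": float(fit.slope),
        "intercept_mm": float(fit.intercept),
        "r_squared": float(fit.rvalue**2) if np.isfinite(fit.rvalue) else 0.0,
        "n_points": int(len(t)),
    }
    return float(v_um_per_h), diagnostics


@dataclass
class RadiusDistribution:
    """Histogram + CDF of edge radii, count- or volume-weighted."""

    weighting: str
    bin_edges: np.ndarray
    mass: np.ndarray           # per-bin weight fraction, sums to 1
    cdf_x: np.ndarray          # sorted radii
    cdf_y: np.ndarray          # cumulative weight fraction at cdf_x
    empty: bool = False

    def cdf(self, radius):
        """Fraction of total weight carried by edges with r <= radius."""
        return np.interp(radius, self.cdf_x, self.cdf_y, left=0.0, right=1.0)


def radius_distribution(
    snapshot: NetworkSnapshot,
    weighting: str = "volume",
    bins=20,
) -> RadiusDistribution:
    """Distribution of edge radii.

    ``weighting='count'`` weights every edge equally; ``'volume'`` weights
    each edge by its cylinder volume ``pi r^2 L`` (the paper-style view of
    where the biovolume sits).
    """
    if weighting not in ("count", "volume"):
        raise ValueError(f"weighting must be 'count' or 'volume', got {weighting!r}")
    if snapshot.n_edges == 0:
        edges = np.asarray([0.0, 1.0])
        return RadiusDistribution(weighting, edges, np.zeros(1), np.asarray([0.0]),
                                  np.asarray([0.0]), empty=True)
    radii = snapshot.edges["radius_um"].to_numpy(float)
    if weighting == "count":
        weights = np.ones_like(radii)
    else:
        _, weights = edge_surface_volume(snapshot.edges["length_um"].to_numpy(float), radii)
    weights = weights / weights.sum()
    hist, bin_edges = np.histogram(radii, bins=bins, weights=weights)
    order = np.argsort(radii, kind="stable")
    cdf_x = radii[order]
    cdf_y = np.cumsum(weights[order])
    cdf_y /= cdf_y[-1]
    return RadiusDistribution(weighting, bin_edges, hist, cdf_x, cdf_y)


# ---------------------------------------------------------------------------
# Snapshot I/O: paired CSV tables and GraphML
# ---------------------------------------------------------------------------

def write_snapshot_csv(directory: str, snapshot: NetworkSnapshot, stem: str) -> list[str]:
    """Write one snapshot as ``<stem>_nodes/_edges/_spores.csv`` in *directory*."""
    os.makedirs(directory, exist_ok=True)
    paths = []
    for kind, table in (("nodes", snapshot.nodes), ("edges", snapshot.edges),
                        ("spores", snapshot.spores)):
        path = os.path.join(directory, f"{stem}_{kind}.csv")
        table.to_csv(path, index=False)
        paths.append(path)
    return paths


def read_snapshot_csv(directory: str, stem: str, time_h: float) -> NetworkSnapshot:
    nodes = pd.read_csv(os.path.join(directory, f"{stem}_nodes.csv"))
    edges = pd.read_csv(os.path.join(directory, f"{stem}_edges.csv"))
    spore_path = os.path.join(directory, f"{stem}_spores.csv")
    spores = pd.read_csv(spore_path) if os.path.exists(spore_path) else pd.DataFrame(columns=SPORE_COLUMNS)
    if spores.empty:
        spores = pd.DataFrame(columns=SPORE_COLUMNS)
    return NetworkSnapshot(time_h=time_h, nodes=nodes, edges=edges, spores=spores)


def write_timelapse_csv(directory: str, snapshots) -> str:
    """Write a snapshot sequence plus an ``index.csv`` (stem, t_h)."""
    os.makedirs(directory, exist_ok=True)
    index_rows = []
    for i, snap in enumerate(snapshots):
        stem = f"snapshot_{i:04d}"
        write_snapshot_csv(directory, snap, stem)
        index_rows.append({"stem": stem, "t_h": snap.time_h})
    index_path = os.path.join(directory, "index.csv")
    pd.DataFrame(index_rows).to_csv(index_path, index=False)
    return index_path


def read_timelapse_csv(directory: str) -> list[NetworkSnapshot]:
    index = pd.read_csv(os.path.join(directory, "index.csv"))
    return [
        read_snapshot_csv(directory, row.stem, float(row.t_h))
        for row in index.itertuples()
    ]


def snapshot_to_graph(snapshot: NetworkSnapshot):
    """NetworkX graph view of a snapshot (for GraphML export)."""
    import networkx as nx

    g = nx.Graph()
    g.graph["time_h"] = snapshot.time_h
    for row in snapshot.nodes.itertuples():
        g.add_node(int(row.node_id), x_mm=float(row.x_mm), y_mm=float(row.y_mm))
    for row in snapshot.edges.itertuples():
        g.add_edge(int(row.source), int(row.target),
                   length_um=float(row.length_um), radius_um=float(row.radius_um))
    return g
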