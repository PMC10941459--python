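"""Synthetic polymer traces and image scenes for pipeline validation.

The generator produces single-chromosome traces whose mean pairwise spatial
distance follows a power law ``d(g) = a * g**s`` of genomic separation
``g`` (Mb), the relationship used throughout the analysis side of the
package.  Each spatial axis is an independent fractional Brownian motion
(fBm) with Hurst index ``H = s`` evaluated at the region coordinates, so a
scaling exponent of 0.5 reduces to a Gaussian random walk while smaller
exponents give the sub-diffusive, crumpled statistics seen for real
chromosomes.  The per-axis amplitude is calibrated so the *expected 3D
Euclidean* distance at 1 Mb equals the step size ``a``: for a 3D isotropic
Gaussian displacement with per-axis standard deviation sigma the mean norm
is ``sigma * E||z||`` with ``E||z|| = sqrt(2) * Gamma(2) / Gamma(3/2)``
(the mean of a chi distribution with 3 degrees of freedom), hence
``sigma = a / E||z||``.

:func:`render_scene` turns traces into a multi-channel image stack
(nuclear stain, chromosome-territory channel, two strain-marker channels,
one diffraction-limited spot channel per region) with exact ground truth,
so segmentation, tracing and strain assignment can be validated end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Trace, VoxelVolume

__all__ = [
    "PolymerParams",
    "SceneSpec",
    "RenderedScene",
    "CHI3_MEAN",
    "default_region_coords",
    "fbm_covariance",
    "simulate_traces",
    "render_scene",
    "traces_to_frame",
    "frame_to_traces",
]

#: Mean Euclidean norm of a standard 3D Gaussian vector (chi distribution,
#: 3 degrees of freedom): sqrt(2) * Gamma(2) / Gamma(3/2) = 2*sqrt(2/pi).
CHI3_MEAN = math.sqrt(2.0) * math.gamma(2.0) / math.gamma(1.5)


def default_region_coords(n_regions: int = 21, spacing_mb: float = 1.0) -> np.ndarray:
    """Evenly spaced region centroids in Mb, starting at ``spacing_mb``.

    The default emulates a whole-chromosome tracing library of 21 regions
    at ~1 Mb spacing along a ~21 Mb chromosome (C. elegans ChrV scale).
    """
    return spacing_mb * np.arange(1, n_regions + 1, dtype=float)


@dataclass
class PolymerParams:
    """Parameters of the fractional-Brownian polymer model.

    Attributes
    ----------
    a
        Step size: expected spatial distance in µm between loci 1 Mb apart.
    s
        Scaling exponent of spatial vs genomic distance (0.5 = random walk).
    region_coords
        Genomic positions of the probe regions in Mb, strictly increasing.
    dropout_rate
        Independent probability that a region focus is missing from a trace.
    seed
        RNG seed; identical seeds give bit-identical traces.
    """

    a: float = 1.0
    s: float = 0.5
    region_coords: np.ndarray = field(default_factory=default_region_coords)
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.region_coords = np.asarray(self.region_coords, dtype=float)
        if self.a <= 0:
            raise ValueError("step size a must be positive")
        if not 0 < self.s < 1:
            raise ValueError("scaling exponent s must lie in (0, 1)")
        if self.region_coords.ndim != 1 or self.region_coords.size < 2:
            raise ValueError("region_coords must be a 1-D array of >= 2 positions")
        if np.any(np.diff(self.region_coords) <= 0):
            raise ValueError("region_coords must be strictly increasing")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")


def fbm_covariance(coords: np.ndarray, hurst: float) -> np.ndarray:
    """Covariance of fractional Brownian motion sampled at ``coords``.

    ``K[i, j] = (t_i^{2H} + t_j^{2H} - |t_i - t_j|^{2H}) / 2`` with B(0) = 0.
    Increments then satisfy ``Var[B(t) - B(u)] = |t - u|^{2H}``.
    """
    t = np.asarray(coords, dtype=float)
    h2 = 2.0 * hurst
    return 0.5 * (
        t[:, None] ** h2 + t[None, :] ** h2 - np.abs(t[:, None] - t[None, :]) ** h2
    )


def simulate_traces(params: PolymerParams, n_traces: int) -> list[Trace]:
    """Draw ``n_traces`` independent polymer traces.

    Each axis is sampled exactly via the Cholesky factor of the R-point fBm
    covariance (R is small, so the factorization is cheap and exact).  The
    per-axis amplitude is ``params.a / CHI3_MEAN`` so that the expected 3D
    distance at 1 Mb separation equals ``params.a``.  Regions are dropped
    independently with probability ``params.dropout_rate``; dropped regions
    become NaN rows.
    """
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    rng = np.random.default_rng(params.seed)
    coords = params.region_coords
    n_regions = coords.size
    sigma = params.a / CHI3_MEAN
    cov = fbm_covariance(coords, params.s)
    # Tiny jitter guards the factorization against round-off for s near 1.
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(n_regions))

    region_ids = np.arange(1, n_regions + 1)
    traces = []
    for i in range(n_traces):
        z = rng.standard_normal((n_regions, 3))
        pos = sigma * (chol @ z)
        if params.dropout_rate > 0:
            drop = rng.random(n_regions) < params.dropout_rate
            pos[drop] = np.nan
        traces.append(
            Trace(
                trace_id=i,
                nucleus_id=i // 2,
                embryo_id=0,
                region_ids=region_ids.copy(),
                positions=pos,
            )
        )
    return traces


@dataclass
class SceneSpec:
    """Geometry and optics of a rendered synthetic embryo field.

    Two chromosome territories (one per strain) are placed inside each
    spherical nucleus; their center-to-center distance is solved so the
    strain-marker masks reach the requested overlap fraction
    ``V(A∩B) / (V(A) + V(B))`` (0 = disjoint, 0.5 = identical).
    """

    n_nuclei: int = 2
    nucleus_diameter_um: float = 5.0
    territory_radius_um: float = 1.2
    traces_per_nucleus: int = 2
    strains: tuple = ("N2", "HI")
    overlap_fraction: float = 0.0
    voxel_size: tuple = (0.1, 0.1, 0.2)
    spot_amplitude: float = 1000.0
    spot_sigma_um: float = 0.12
    background: float = 10.0
    noise_sd: float = 0.0
    margin_um: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if not 0 <= self.overlap_fraction <= 0.5:
            raise ValueError("overlap fraction must lie in [0, 0.5]")
        if self.traces_per_nucleus > len(self.strains):
            raise ValueError("need one strain label per trace in a nucleus")


@dataclass
class RenderedScene:
    """Output bundle of :func:`render_scene` with full ground truth."""

    dapi: VoxelVolume
    territory: VoxelVolume
    markers: dict  # strain -> binary VoxelVolume
    spots: dict  # region_id -> VoxelVolume
    nucleus_labels: VoxelVolume
    truth_traces: list
    truth_table: pd.DataFrame


def _sphere_overlap_ratio(d: float, r: float) -> float:
    """Overlap fraction V(A∩B)/(V(A)+V(B)) of two equal spheres of radius
    r whose centers are d apart (lens-volume formula)."""
    if d >= 2 * r:
        return 0.0
    lens = math.pi * (2 * r - d) ** 2 * (d**2 + 4 * d * r) / (12 * d) if d > 0 else (
        4.0 / 3.0 * math.pi * r**3
    )
    total = 2 * (4.0 / 3.0) * math.pi * r**3
    return lens / total


def _solve_center_distance(overlap_fraction: float, r: float) -> float:
    """Invert the sphere-overlap formula by bisection."""
    if overlap_fraction <= 0:
        return 2.0 * r
    if overlap_fraction >= 0.5:
        return 0.0
    lo, hi = 0.0, 2.0 * r
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _sphere_overlap_ratio(mid, r) > overlap_fraction:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _ball_mask(shape, center_um, radius_um, voxel_size):
    dx, dy, dz = voxel_size
    nz, ny, nx = shape
    z = (np.arange(nz) + 0.5) * dz
    y = (np.arange(ny) + 0.5) * dy
    x = (np.arange(nx) + 0.5) * dx
    cz, cy, cx = center_um[2], center_um[1], center_um[0]
    dist2 = (
        ((z - cz) ** 2)[:, None, None]
        + ((y - cy) ** 2)[None, :, None]
        + ((x - cx) ** 2)[None, None, :]
    )
    return dist2 <= radius_um**2


def render_scene(spec: SceneSpec, traces: list[Trace] | None = None) -> RenderedScene:
    """Render a synthetic multi-channel image stack from polymer traces.

    Traces are recentred and, if necessary, uniformly shrunk to fit inside
    their assigned territory sphere; the returned ground truth carries the
    placed (rendered) coordinates.  When ``traces`` is None, random-walk
    traces with 21 regions are simulated internally.

    Raises
    ------
    ValueError
        If the requested territory overlap cannot be reached inside the
        nucleus (the two territory spheres would have to sit further apart
        than the nucleus allows); the message reports the achievable
        minimum overlap fraction.
    """
    rng = np.random.default_rng(spec.seed)
    n_per = spec.traces_per_nucleus
    if traces is None:
        params = PolymerParams(a=0.4, s=0.5, seed=spec.seed)
        traces = simulate_traces(params, spec.n_nuclei * n_per)
    if len(traces) != spec.n_nuclei * n_per:
        raise ValueError(
            f"expected {spec.n_nuclei * n_per} traces, got {len(traces)}"
        )

    r_nuc = spec.nucleus_diameter_um / 2.0
    r_ter = spec.territory_radius_um
    d_centers = _solve_center_distance(spec.overlap_fraction, r_ter)
    if d_centers / 2.0 + r_ter > r_nuc:
        max_d = 2.0 * (r_nuc - r_ter)
        if max_d < 0:
            raise ValueError("territory radius exceeds nucleus radius")
        achievable = _sphere_overlap_ratio(max_d, r_ter)
        raise ValueError(
            "requested overlap fraction unreachable inside the nucleus; "
            f"achievable minimum is {achievable:.3f}"
        )

    # Nuclei on a single row along x, separated by a margin.
    pitch = spec.nucleus_diameter_um + 2 * spec.margin_um
    size_x = spec.n_nuclei * pitch
    size_y = size_z = pitch
    dx, dy, dz = spec.voxel_size
    shape = (
        int(round(size_z / dz)),
        int(round(size_y / dy)),
        int(round(size_x / dx)),
    )

    dapi = np.zeros(shape, dtype=float)
    territory = np.zeros(shape, dtype=float)
    nucleus_labels = np.zeros(shape, dtype=np.int32)
    marker = {s: np.zeros(shape, dtype=bool) for s in spec.strains[:n_per]}
    region_ids = traces[0].region_ids
    spots = {int(rid): np.zeros(shape, dtype=float) for rid in region_ids}

    placed = []
    rows = []
    for inuc in range(spec.n_nuclei):
        center = np.array([(inuc + 0.5) * pitch, size_y / 2.0, size_z / 2.0])
        nuc_mask = _ball_mask(shape, center, r_nuc, spec.voxel_size)
        dapi[nuc_mask] += 1.0
        nucleus_labels[nuc_mask] = inuc + 1

        # Territory centers along y so nuclei stay separable along x.
        offsets = np.array(
            [[0.0, -d_centers / 2.0, 0.0], [0.0, d_centers / 2.0, 0.0]]
        )[:n_per]
        for itr in range(n_per):
            trace = traces[inuc * n_per + itr]
            strain = spec.strains[itr]
            t_center = center + offsets[itr]
            ter_mask = _ball_mask(shape, t_center, r_ter, spec.voxel_size)
            territory[ter_mask] += 1.0
            marker[strain] |= ter_mask

            # Recenter and shrink the trace into its territory sphere.
            pos = trace.positions.copy()
            obs = ~np.isnan(pos).any(axis=1)
            centroid = np.nanmean(pos, axis=0)
            pos = pos - centroid
            max_r = np.nanmax(np.linalg.norm(pos[obs], axis=1)) if obs.any() else 0.0
            fit_r = 0.85 * r_ter
            if max_r > fit_r:
                pos *= fit_r / max_r
            pos = pos + t_center
            new = Trace(
                trace_id=trace.trace_id,
                nucleus_id=inuc + 1,
                embryo_id=trace.embryo_id,
                region_ids=trace.region_ids.copy(),
                positions=pos,
                strain=strain,
                territory_id=inuc * n_per + itr + 1,
            )
            placed.append(new)
            for rid, p in zip(new.region_ids, pos):
                if np.isnan(p).any():
                    continue
                _add_gaussian_spot(
                    spots[int(rid)], p, spec.spot_amplitude, spec.spot_sigma_um,
                    spec.voxel_size,
                )
                rows.append(
                    {
                        "embryo_id": new.embryo_id,
                        "nucleus_id": new.nucleus_id,
                        "trace_id": new.trace_id,
                        "region_id": int(rid),
                        "x_um": p[0],
                        "y_um": p[1],
                        "z_um": p[2],
                        "strain": strain,
                    }
                )

    dapi = spec.background + 100.0 * dapi
    territory = spec.background + 100.0 * territory
    for arr in spots.values():
        arr += spec.background
    if spec.noise_sd > 0:
        dapi += rng.normal(0, spec.noise_sd, shape)
        territory += rng.normal(0, spec.noise_sd, shape)
        for arr in spots.values():
            arr += rng.normal(0, spec.noise_sd, shape)

    vx = spec.voxel_size
    return RenderedScene(
        dapi=VoxelVolume(dapi, vx),
        territory=VoxelVolume(territory, vx),
        markers={s: VoxelVolume(m, vx) for s, m in marker.items()},
        spots={r: VoxelVolume(a, vx) for r, a in spots.items()},
        nucleus_labels=VoxelVolume(nucleus_labels, vx),
        truth_traces=placed,
        truth_table=pd.DataFrame(rows),
    )


def _add_gaussian_spot(arr, center_um, amplitude, sigma_um, voxel_size):
    """Add an isotropic 3D Gaussian at ``center_um`` within a small window."""
    dx, dy, dz = voxel_size
    nz, ny, nx = arr.shape
    half = 4.0 * sigma_um
    iz0 = max(int((center_um[2] - half) / dz), 0)
    iz1 = min(int((center_um[2] + half) / dz) + 2, nz)
    iy0 = max(int((center_um[1] - half) / dy), 0)
    iy1 = min(int((center_um[1] + half) / dy) + 2, ny)
    ix0 = max(int((center_um[0] - half) / dx), 0)
    ix1 = min(int((center_um[0] + half) / dx) + 2, nx)
    if iz0 >= iz1 or iy0 >= iy1 or ix0 >= ix1:
        return
    z = (np.arange(iz0, iz1) + 0.5) * dz - center_um[2]
    y = (np.arange(iy0, iy1) + 0.5) * dy - center_um[1]
    x = (np.arange(ix0, ix1) + 0.5) * dx - center_um[0]
    g = np.exp(
        -(
            (z**2)[:, None, None]
            + (y**2)[None, :, None]
            + (x**2)[None, None, :]
        )
        / (2.0 * sigma_um**2)
    )
    arr[iz0:iz1, iy0:iy1, ix0:ix1] += amplitude * g


def traces_to_frame(traces: list[Trace]) -> pd.DataFrame:
    """Long-format trace table (one row per observed region)."""
    rows = []
    for tr in traces:
        for rid, p in zip(tr.region_ids, tr.positions):
            if np.isnan(p).any():
                continue
            rows.append(
                {
                    "embryo_id": tr.embryo_id,
                    "nucleus_id": tr.nucleus_id,
                    "trace_id": tr.trace_id,
                    "region_id": int(rid),
                    "x_um": p[0],
                    "y_um": p[1],
                    "z_um": p[2],
                    "strain": tr.strain,
                    "exclusion_reason": tr.exclusion_reason,
                }
            )
    return pd.DataFrame(rows)


def frame_to_traces(
    frame: pd.DataFrame, region_ids: np.ndarray | None = None
) -> list[Trace]:
    """Rebuild Trace objects from a long-format table.

    ``region_ids`` fixes the full region set; regions absent from a trace's
    rows become NaN (dropout).
    """
    if region_ids is None:
        region_ids = np.sort(frame["region_id"].unique())
    region_ids = np.asarray(region_ids, dtype=int)
    index = {int(r): i for i, r in enumerate(region_ids)}
    traces = []
    keys = ["embryo_id", "nucleus_id", "trace_id"]
    for (emb, nuc, tid), grp in frame.groupby(keys, sort=True):
        pos = np.full((region_ids.size, 3), np.nan)
        mult: dict = {}
        for _, row in grp.iterrows():
            i = index[int(row["region_id"])]
            pos[i] = (row["x_um"], row["y_um"], row["z_um"])
            mult[int(row["region_id"])] = mult.get(int(row["region_id"]), 0) + 1
        strain = grp["strain"].iloc[0] if "strain" in grp else "unassigned"
        traces.append(
            Trace(
                trace_id=int(tid),
                nucleus_id=int(nuc),
                embryo_id=int(emb),
                region_ids=region_ids.copy(),
                positions=pos,
                strain=str(strain),
                multiplicity={k: v for k, v in mult.items() if v > 1},
            )
        )
    return traces
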