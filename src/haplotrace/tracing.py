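"""Focus detection and connect-the-dots chromosome tracing.

Diffraction-limited foci, one imaging round per probe region, are detected
inside segmented chromosome-territory volumes and linked into traces by a
nearest-neighbor rule: the focus of region n connects to the *closest*
focus detected for the next observed region, on the assumption that a more
distant candidate belongs to the other homolog.  Quality-control drop-out
criteria then exclude traces arising from mis-segmentation, in a fixed
precedence order so every excluded trace has exactly one reason.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import squareform, pdist

from .core import Trace, VoxelVolume

__all__ = [
    "Focus",
    "detect_foci",
    "trace_chromosomes",
    "pairwise_distance_matrix",
    "apply_dropout_criteria",
]


@dataclass
class Focus:
    """One detected region focus in a registered channel."""

    region_id: int
    position: np.ndarray  # (x, y, z) µm
    intensity: float
    nucleus_id: int = 0
    territory_id: int = 0


def detect_foci(
    region_channel: VoxelVolume,
    region_id: int,
    threshold: float,
    territory_labels: VoxelVolume | None = None,
    nucleus_labels: VoxelVolume | None = None,
    min_separation_vox: int = 3,
) -> list[Focus]:
    """Find local intensity maxima above ``threshold`` and refine them.

    Each maximum is refined to the intensity-weighted centroid of its
    3x3x3 neighborhood (background-subtracted by the channel minimum) and
    converted to µm.  Foci are tagged with the enclosing territory and
    nucleus label; a focus falling on background is attributed to the
    nearest labeled territory voxel.
    """
    data = region_channel.data.astype(float)
    if data.max() <= threshold:
        return []
    footprint = np.ones((min_separation_vox,) * 3, dtype=bool)
    local_max = data == ndimage.maximum_filter(data, footprint=footprint)
    peaks = np.argwhere(local_max & (data > threshold))

    ter_near = nuc_near = None
    if territory_labels is not None and np.any(territory_labels.data > 0):
        ter_near = _nearest_label_lookup(territory_labels.data)
    if nucleus_labels is not None and np.any(nucleus_labels.data > 0):
        nuc_near = _nearest_label_lookup(nucleus_labels.data)

    base = data.min()
    foci = []
    for pk in peaks:
        lo = np.maximum(pk - 1, 0)
        hi = np.minimum(pk + 2, data.shape)
        win = data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] - base
        grid = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].astype(float)
        w = win.clip(min=0)
        if w.sum() <= 0:
            centroid = pk.astype(float)
        else:
            centroid = (grid * w).sum(axis=(1, 2, 3)) / w.sum()
        pos = region_channel.index_to_um(centroid[None, :])[0]
        tid = int(ter_near[tuple(pk)]) if ter_near is not None else 0
        nid = int(nuc_near[tuple(pk)]) if nuc_near is not None else 0
        foci.append(
            Focus(
                region_id=region_id,
                position=pos,
                intensity=float(data[tuple(pk)]),
                nucleus_id=nid,
                territory_id=tid,
            )
        )
    return foci


def _nearest_label_lookup(labels: np.ndarray) -> np.ndarray:
    """Volume mapping every voxel to the nearest nonzero label."""
    _, (iz, iy, ix) = ndimage.distance_transform_edt(
        labels == 0, return_indices=True
    )
    return labels[iz, iy, ix]


def trace_chromosomes(
    foci: list[Focus],
    region_ids: np.ndarray,
    embryo_id: int = 0,
) -> list[Trace]:
    """Chain detected foci into one trace per territory.

    Within each territory, chaining proceeds in genomic order from the
    lowest-index region present: the current position links to the nearest
    focus of the next observed region (missing regions are skipped, so the
    link jumps directly to the next region with candidates).  When several
    foci exist for the starting region, the brightest seeds the chain.
    Regions with multiple candidate foci inside one territory are recorded
    in the trace's multiplicity map, flagging it for the duplicate-region
    drop-out criterion downstream.
    """
    region_ids = np.asarray(region_ids, dtype=int)
    by_territory: dict = {}
    for f in foci:
        by_territory.setdefault(f.territory_id, []).append(f)

    traces = []
    for tid in sorted(by_territory):
        group = by_territory[tid]
        by_region: dict = {}
        for f in group:
            by_region.setdefault(f.region_id, []).append(f)
        present = [r for r in region_ids if r in by_region]
        if not present:
            continue
        pos = np.full((region_ids.size, 3), np.nan)
        mult = {r: len(by_region[r]) for r in present if len(by_region[r]) > 1}
        idx = {int(r): i for i, r in enumerate(region_ids)}

        start = max(by_region[present[0]], key=lambda f: f.intensity)
        pos[idx[present[0]]] = start.position
        current = start.position
        for r in present[1:]:
            cands = by_region[r]
            nearest = min(
                cands, key=lambda f: float(np.linalg.norm(f.position - current))
            )
            pos[idx[r]] = nearest.position
            current = nearest.position
        nucleus_id = group[0].nucleus_id
        traces.append(
            Trace(
                trace_id=tid,
                nucleus_id=nucleus_id,
                embryo_id=embryo_id,
                region_ids=region_ids.copy(),
                positions=pos,
                territory_id=tid,
                multiplicity=mult,
            )
        )
    return traces


def pairwise_distance_matrix(trace: Trace) -> np.ndarray:
    """3D Euclidean distances between all region pairs of one trace.

    Missing regions give NaN rows/columns; the diagonal is zero for
    observed regions.
    """
    if trace.n_observed < 2:
        raise ValueError("trace must observe >= 2 regions")
    pos = trace.positions
    n = pos.shape[0]
    d = np.full((n, n), np.nan)
    obs = trace.observed
    io = np.where(obs)[0]
    if io.size >= 2:
        sub = squareform(pdist(pos[io]))
        d[np.ix_(io, io)] = sub
    else:
        d[io[0], io[0]] = 0.0
    return d


@dataclass
class ExclusionLedger:
    """Per-category exclusion counts for a trace population.

    The five mutually exclusive categories follow the fixed precedence
    order of :func:`apply_dropout_criteria`; ``too_short`` is tallied
    separately (it is applied before classification, as a minimum-length
    requirement, not as one of the five accounting categories).
    """

    total: int = 0
    classified_n2: int = 0
    classified_hi: int = 0
    duplicate_region: int = 0
    too_many_traces: int = 0
    too_many_hi: int = 0
    too_many_n2: int = 0
    ambiguous_tie: int = 0
    too_short: int = 0

    @property
    def excluded(self) -> int:
        return (
            self.duplicate_region
            + self.too_many_traces
            + self.too_many_hi
            + self.too_many_n2
            + self.ambiguous_tie
        )

    def category_counts(self) -> dict:
        return {
            "duplicate_region": self.duplicate_region,
            "too_many_traces": self.too_many_traces,
            "too_many_per_strain_HI": self.too_many_hi,
            "too_many_per_strain_N2": self.too_many_n2,
            "ambiguous_tie": self.ambiguous_tie,
        }


def apply_dropout_criteria(
    traces: list[Trace],
    min_regions: int = 4,
    max_traces_per_nucleus: int = 4,
    max_traces_per_strain: int = 2,
) -> tuple[list[Trace], ExclusionLedger]:
    """Apply the quality-control drop-out criteria and account for them.

    Traces observing fewer than ``min_regions`` regions are removed first
    (``too_short``) and do not enter the five-category accounting.  The
    remaining traces are then excluded, each by the *first* matching
    criterion in precedence order:

    1. any region present more than once in the trace (duplicate_region);
    2. more than ``max_traces_per_nucleus`` traces in the nucleus
       (too_many_traces) — more than four chromosome copies is
       biologically impossible in a wild-type diploid and indicates
       territory over-segmentation;
    3./4. more than ``max_traces_per_strain`` traces carrying the same
       strain label in the nucleus (too_many_per_strain);
    5. traces left unresolved by strain assignment (ambiguous_tie).

    Traces whose ``strain`` is ``'ambiguous_tie'`` on entry (set by the
    haplotyping step) are counted under category 5.  Returns the kept
    traces and the populated :class:`ExclusionLedger`.
    """
    ledger = ExclusionLedger()
    pool = []
    for t in traces:
        if t.n_observed < min_regions:
            t.exclusion_reason = "too_short"
            ledger.too_short += 1
        else:
            pool.append(t)
    ledger.total = len(pool)

    by_nucleus: dict = {}
    for t in pool:
        by_nucleus.setdefault((t.embryo_id, t.nucleus_id), []).append(t)

    kept = []
    for t in pool:
        nucleus = by_nucleus[(t.embryo_id, t.nucleus_id)]
        if t.has_duplicate_region:
            t.exclusion_reason = "duplicate_region"
            ledger.duplicate_region += 1
        elif len(nucleus) > max_traces_per_nucleus:
            t.exclusion_reason = "too_many_traces"
            ledger.too_many_traces += 1
        elif (
            t.strain in ("N2", "HI")
            and sum(u.strain == t.strain for u in nucleus) > max_traces_per_strain
        ):
            t.exclusion_reason = "too_many_per_strain"
            if t.strain == "HI":
                ledger.too_many_hi += 1
            else:
                ledger.too_many_n2 += 1
        elif t.strain == "ambiguous_tie":
            t.exclusion_reason = "ambiguous_tie"
            ledger.ambiguous_tie += 1
        else:
            kept.append(t)

    ledger.classified_n2 = sum(t.strain == "N2" for t in kept)
    ledger.classified_hi = sum(t.strain == "HI" for t in kept)
    return kept, ledger
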