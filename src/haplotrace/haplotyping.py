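"""Parent-of-origin assignment of traces from strain-marker territories.

In inter-strain crosses the two homologs are marked by strain-specific
probe sets (Bristol N2 vs Hawai'ian HI).  Each traced region votes for the
strain whose marker volume it lies inside or closest to — measured as the
smallest Euclidean distance to the marker mask's boundary voxels — and a
trace is labeled by the majority of its region votes.  Equal votes leave
the trace ambiguous and it is removed.  The module also produces the
exclusion accounting report (per-category counts and percentages of the
total trace population).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import Trace, VoxelVolume
from .tracing import ExclusionLedger

__all__ = [
    "ExclusionLedger",
    "mask_boundary_voxels",
    "assign_strain",
    "assign_strains",
    "exclusion_accounting",
]

# 6-connected structuring element: face neighbors only.
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


def mask_boundary_voxels(mask: VoxelVolume) -> np.ndarray:
    """(n, 3) µm coordinates of the 6-connected surface voxels of a mask."""
    m = mask.data.astype(bool)
    interior = ndimage.binary_erosion(m, structure=_STRUCT6, border_value=0)
    boundary = m & ~interior
    idx = np.argwhere(boundary)
    if idx.size == 0:
        return np.empty((0, 3))
    return mask.index_to_um(idx)


def _region_distances(positions: np.ndarray, mask: VoxelVolume) -> np.ndarray:
    """Distance of each position to the mask: 0 inside, else the smallest
    Euclidean distance to a boundary voxel center; inf if the mask is
    empty."""
    n = positions.shape[0]
    if not mask.data.any():
        return np.full(n, np.inf)
    boundary = mask_boundary_voxels(mask)
    tree = cKDTree(boundary)
    dist, _ = tree.query(positions)
    idx = mask.um_to_index(positions)
    shape = mask.data.shape
    inside = np.zeros(n, dtype=bool)
    ok = (
        (idx >= 0).all(axis=1)
        & (idx[:, 0] < shape[0])
        & (idx[:, 1] < shape[1])
        & (idx[:, 2] < shape[2])
    )
    inside[ok] = mask.data[idx[ok, 0], idx[ok, 1], idx[ok, 2]].astype(bool)
    dist = np.where(inside, 0.0, dist)
    return dist


def assign_strain(
    trace: Trace, n2_mask: VoxelVolume, hi_mask: VoxelVolume
) -> str:
    """Label one trace as 'N2', 'HI' or 'ambiguous_tie' by region votes.

    Each observed region votes for the strain-marker volume it is inside
    (distance 0) or nearest to by boundary distance; regions exactly
    equidistant abstain.  The trace takes the majority label; equal vote
    counts — including the degenerate case of two empty masks — give
    ``'ambiguous_tie'``.
    """
    obs = trace.observed
    positions = trace.positions[obs]
    if positions.shape[0] == 0:
        return "ambiguous_tie"
    d_n2 = _region_distances(positions, n2_mask)
    d_hi = _region_distances(positions, hi_mask)
    finite = np.isfinite(d_n2) | np.isfinite(d_hi)
    votes_n2 = int(np.sum(finite & (d_n2 < d_hi)))
    votes_hi = int(np.sum(finite & (d_hi < d_n2)))
    if votes_n2 > votes_hi:
        return "N2"
    if votes_hi > votes_n2:
        return "HI"
    return "ambiguous_tie"


def assign_strains(
    traces: list[Trace],
    strain_masks: dict,
) -> list[Trace]:
    """Assign strains to all traces, in place.

    ``strain_masks`` maps nucleus_id to ``{"N2": VoxelVolume, "HI":
    VoxelVolume}``.  Traces in nuclei without masks stay unassigned.
    """
    for t in traces:
        masks = strain_masks.get(t.nucleus_id)
        if masks is None:
            continue
        t.strain = assign_strain(t, masks["N2"], masks["HI"])
    return traces


def exclusion_accounting(ledger: ExclusionLedger) -> pd.DataFrame:
    """Per-category exclusion report with percentages of all traces.

    Percentages are of the total trace population, rounded to one decimal.
    Raises if the ledger violates count conservation (classified + five
    exclusion categories must equal the total).
    """
    counts = ledger.category_counts()
    expected_excluded = ledger.total - ledger.classified_n2 - ledger.classified_hi
    if ledger.excluded != expected_excluded:
        raise ValueError(
            f"ledger does not conserve counts: {ledger.excluded} excluded vs "
            f"{expected_excluded} = total - classified"
        )
    rows = []
    for name, c in counts.items():
        pct = round(100.0 * c / ledger.total, 1) if ledger.total else 0.0
        rows.append({"category": name, "count": c, "percent": pct})
    overall = round(100.0 * ledger.excluded / ledger.total, 1) if ledger.total else 0.0
    rows.append(
        {"category": "total_excluded", "count": ledger.excluded, "percent": overall}
    )
    return pd.DataFrame(rows)
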