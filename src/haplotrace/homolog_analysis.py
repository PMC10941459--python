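"""Homolog territory overlap and inter-homolog distance analysis.

Territory overlap asks how much the two homologous chromosome territories
share nuclear volume: the overlap ratio is overlapping voxels divided by
the *summed* voxel counts of both strain-marker masks, so it ranges 0
(disjoint) to 0.5 (identical masks).  Ratios below a cutoff (default 5%,
absorbing low-level cross-hybridization background) count as
non-overlapping.  Inter-homolog distance matrices ask whether equivalent
loci on the two homologs align: for nuclei carrying exactly two traces,
distances from every region on one homolog to every region on the other
are averaged across nuclei.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .core import Trace, VoxelVolume

__all__ = [
    "OverlapRecord",
    "HomologDistanceMatrix",
    "territory_overlap",
    "overlap_summary",
    "stage_overlap_comparison",
    "interhomolog_distances",
]


@dataclass
class OverlapRecord:
    """Voxel bookkeeping of one nucleus's homolog-territory overlap."""

    nucleus_id: int
    stage_bin: str
    voxels_a: int
    voxels_b: int
    voxels_overlap: int
    ratio: float
    no_overlap: bool


@dataclass
class HomologDistanceMatrix:
    """Mean region-by-region distances across homolog pairs.

    Rows index homolog 1 (the maternal strain for hybrids), columns
    homolog 2.  ``symmetrized`` marks homozygote input, where the two
    orderings of each pair are averaged and the matrix is symmetric.
    """

    mean: np.ndarray
    counts: np.ndarray
    region_ids: np.ndarray
    symmetrized: bool


def territory_overlap(
    mask_a: VoxelVolume,
    mask_b: VoxelVolume,
    cutoff: float = 0.05,
    nucleus_id: int = 0,
    stage_bin: str = "",
) -> OverlapRecord | None:
    """Overlap record for one nucleus's two strain-marker masks.

    ratio = overlap voxels / (voxels A + voxels B), in [0, 0.5]; below
    ``cutoff`` the homologs count as non-overlapping.  Returns None (with
    a warning) when both masks are empty.
    """
    a = mask_a.data.astype(bool)
    b = mask_b.data.astype(bool)
    va, vb = int(a.sum()), int(b.sum())
    if va + vb == 0:
        warnings.warn(f"nucleus {nucleus_id}: both strain masks empty; dropped")
        return None
    vo = int((a & b).sum())
    ratio = vo / (va + vb)
    return OverlapRecord(
        nucleus_id=nucleus_id,
        stage_bin=stage_bin,
        voxels_a=va,
        voxels_b=vb,
        voxels_overlap=vo,
        ratio=ratio,
        no_overlap=ratio < cutoff,
    )


def overlap_summary(
    records: list[OverlapRecord], high_threshold: float = 0.15
) -> dict:
    """Dataset-level summary of overlap records.

    Reports the fraction of nuclei with no overlap (ratio below the
    cutoff) and, among the overlapping remainder, the fraction whose
    ratio exceeds ``high_threshold``.
    """
    n = len(records)
    if n == 0:
        return {"n": 0, "frac_no_overlap": np.nan, "frac_high_overlap": np.nan}
    none = [r for r in records if r.no_overlap]
    rest = [r for r in records if not r.no_overlap]
    frac_high = (
        sum(r.ratio > high_threshold for r in rest) / len(rest) if rest else np.nan
    )
    return {
        "n": n,
        "frac_no_overlap": len(none) / n,
        "frac_high_overlap": frac_high,
    }


def stage_overlap_comparison(
    records: list[OverlapRecord],
    merge_first_into: tuple | None = ("1-4", "5-16", "<=16"),
    min_records: int = 3,
) -> pd.DataFrame:
    """Pairwise two-sample Kolmogorov-Smirnov tests of overlap ratios
    between developmental stage bins.

    ``merge_first_into = (bin_a, bin_b, merged_label)`` folds a sparse
    early bin into the next one before testing (sample-size requirement of
    the K-S test).  Bin pairs where either side has fewer than
    ``min_records`` ratios are skipped with a warning.
    """
    by_bin: dict = {}
    for r in records:
        by_bin.setdefault(r.stage_bin, []).append(r.ratio)
    if merge_first_into is not None:
        a, b, label = merge_first_into
        if a in by_bin:
            merged = by_bin.pop(a) + by_bin.pop(b, [])
            by_bin[label] = merged
    bins = sorted(by_bin)
    if len(bins) < 2:
        raise ValueError("need >= 2 stage bins after merging")
    rows = []
    for b1, b2 in combinations(bins, 2):
        x, y = by_bin[b1], by_bin[b2]
        if len(x) < min_records or len(y) < min_records:
            warnings.warn(f"skipping {b1} vs {b2}: fewer than {min_records} records")
            continue
        res = stats.ks_2samp(x, y)
        rows.append(
            {
                "bin_a": b1,
                "bin_b": b2,
                "n_a": len(x),
                "n_b": len(y),
                "ks_statistic": float(res.statistic),
                "pvalue": float(res.pvalue),
            }
        )
    return pd.DataFrame(rows)


def interhomolog_distances(
    traces: list[Trace],
    max_partner_gap_um: float = 6.0,
    hybrid: bool = True,
    maternal_strain: str | None = None,
) -> HomologDistanceMatrix:
    """Mean distances between all regions of one homolog and the other.

    Only nuclei containing exactly two kept traces contribute (pre-
    replication nuclei with one copy of each homolog).  Partner pairs
    whose *minimum* cross-trace region distance exceeds
    ``max_partner_gap_um`` are discarded as nucleus mis-segmentation: two
    genuine homologs share a ~5 µm nucleus, so a pair nowhere within 6 µm
    cannot be in the same nucleus.  For hybrids, rows index the maternal
    strain's homolog (``maternal_strain`` required); for homozygotes the
    two orderings are averaged, giving a symmetric matrix.
    """
    if hybrid and maternal_strain is None:
        raise ValueError("maternal_strain is required for hybrid input")
    kept = [t for t in traces if not t.excluded]
    by_nucleus: dict = {}
    for t in kept:
        by_nucleus.setdefault((t.embryo_id, t.nucleus_id), []).append(t)

    region_ids = kept[0].region_ids if kept else np.array([], dtype=int)
    n = region_ids.size
    total = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    for pair in by_nucleus.values():
        if len(pair) != 2:
            continue
        t1, t2 = pair
        if hybrid:
            if {t1.strain, t2.strain} != {"N2", "HI"}:
                continue
            if t2.strain == maternal_strain:
                t1, t2 = t2, t1
        d = cdist(t1.positions, t2.positions)  # NaN rows propagate
        finite = np.isfinite(d)
        if not finite.any() or np.nanmin(d) > max_partner_gap_um:
            continue
        if hybrid:
            total[finite] += d[finite]
            counts[finite] += 1
        else:
            for mat in (d, d.T):
                f = np.isfinite(mat)
                total[f] += mat[f]
                counts[f] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, total / np.maximum(counts, 1), np.nan)
    if not hybrid:
        counts = counts // 1  # both orderings already accumulated
    return HomologDistanceMatrix(mean, counts, region_ids, symmetrized=not hybrid)
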