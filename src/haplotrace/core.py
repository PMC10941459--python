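"""Core containers shared across the tracing pipeline.

Coordinates are in micrometers (µm) throughout, with the origin at the
volume corner, axes ordered (x, y, z), and voxel positions taken at voxel
centers: ``x = (index + 0.5) * voxel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Strain labels used throughout: Bristol (N2) and Hawai'ian (HI).
STRAINS = ("N2", "HI")

#: Exclusion categories for traces, in the precedence order applied by
#: :func:`haplotrace.tracing.apply_dropout_criteria`.
EXCLUSION_REASONS = (
    "none",
    "too_short",
    "duplicate_region",
    "too_many_traces",
    "too_many_per_strain",
    "ambiguous_tie",
)


@dataclass
class Trace:
    """One chromosome's ordered 3D path over a fixed set of probe regions.

    Parameters
    ----------
    region_ids
        Region identifiers in genomic order, shape ``(R,)``.
    positions
        ``(R, 3)`` array of (x, y, z) positions in µm.  Rows of NaN mark
        regions that were not detected (dropout).
    multiplicity
        Number of candidate foci seen for each region inside the trace's
        territory.  A value > 1 for any region marks the trace as carrying
        a duplicated region.
    """

    trace_id: int
    nucleus_id: int
    embryo_id: int
    region_ids: np.ndarray
    positions: np.ndarray
    strain: str = "unassigned"
    exclusion_reason: str = "none"
    territory_id: int = -1
    multiplicity: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.region_ids = np.asarray(self.region_ids, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (self.region_ids.size, 3):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match "
                f"{self.region_ids.size} regions"
            )
        if np.any(np.diff(self.region_ids) <= 0):
            raise ValueError("region_ids must be strictly increasing")

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of regions with a detected position."""
        return ~np.isnan(self.positions).any(axis=1)

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())

    @property
    def has_duplicate_region(self) -> bool:
        return any(m > 1 for m in self.multiplicity.values())

    @property
    def excluded(self) -> bool:
        return self.exclusion_reason != "none"


@dataclass
class VoxelVolume:
    """A 3D grid of intensities or integer labels with anisotropic voxels.

    ``data`` is indexed ``[z, y, x]`` (the axis order of image stacks);
    ``voxel_size`` is ``(dx, dy, dz)`` in µm.
    """

    data: np.ndarray
    voxel_size: tuple = (0.1, 0.1, 0.2)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("VoxelVolume data must be 3-dimensional")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")

    @property
    def voxel_volume_um3(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz

    def index_to_um(self, zyx_indices: np.ndarray) -> np.ndarray:
        """Convert ``(n, 3)`` voxel indices ``[z, y, x]`` to (x, y, z) µm."""
        idx = np.atleast_2d(np.asarray(zyx_indices, dtype=float))
        dx, dy, dz = self.voxel_size
        out = np.empty_like(idx)
        out[:, 0] = (idx[:, 2] + 0.5) * dx
        out[:, 1] = (idx[:, 1] + 0.5) * dy
        out[:, 2] = (idx[:, 0] + 0.5) * dz
        return out

    def um_to_index(self, xyz_um: np.ndarray) -> np.ndarray:
        """Convert (x, y, z) µm coordinates to nearest ``[z, y, x]`` indices."""
        pos = np.atleast_2d(np.asarray(xyz_um, dtype=float))
        dx, dy, dz = self.voxel_size
        iz = np.round(pos[:, 2] / dz - 0.5).astype(int)
        iy = np.round(pos[:, 1] / dy - 0.5).astype(int)
        ix = np.round(pos[:, 0] / dx - 0.5).astype(int)
        return np.stack([iz, iy, ix], axis=1)
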