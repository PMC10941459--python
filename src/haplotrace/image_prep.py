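"""Chromatic registration, watershed segmentation and embryo staging.

Segmentation follows the classical marker-controlled recipe for touching
convex objects: background subtraction, smoothing, binarization, Euclidean
distance transform of the binary foreground, then watershed from the
distance-transform maxima.  Nuclei (nuclear stain) and chromosome
territories (whole-chromosome probe signal) are segmented with the same
recipe, territories being additionally confined to the nuclear mask.
Chromatic aberration between acquisition channels is corrected with an
affine transform fitted to matched fiducial-bead coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, measure, segmentation
from skimage.feature import peak_local_max

from .core import VoxelVolume

__all__ = [
    "Transform3D",
    "NucleusRecord",
    "fit_chromatic_transform",
    "segment_nuclei",
    "filter_interphase",
    "segment_territories",
    "stage_embryo",
    "DEFAULT_STAGE_BINS",
]


@dataclass
class Transform3D:
    """Affine map ``y = linear @ x + translation`` between channels (µm)."""

    linear: np.ndarray
    translation: np.ndarray
    rms_residual: float = 0.0

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.linear.T + self.translation


@dataclass
class NucleusRecord:
    """Size and shape summary of one segmented nucleus."""

    nucleus_id: int
    embryo_id: int
    voxel_count: int
    diameter_um: float  # equivalent-sphere diameter (6V/pi)^(1/3)
    sphericity: float
    interphase: bool
    stage_bin: str = ""


def fit_chromatic_transform(
    source: np.ndarray, target: np.ndarray
) -> Transform3D:
    """Least-squares affine aligning bead positions ``source`` -> ``target``.

    With at least four non-coplanar bead pairs the full 3D affine (shift,
    scale, shear, rotation) is solved in closed form; degenerate geometry
    falls back to a translation-only fit (centroid difference) with a
    warning.  The RMS residual over the fitted pairs is reported.
    """
    src = np.atleast_2d(np.asarray(source, dtype=float))
    tgt = np.atleast_2d(np.asarray(target, dtype=float))
    if src.shape != tgt.shape or src.shape[1] != 3:
        raise ValueError("source and target must be matched (n, 3) arrays")
    n = src.shape[0]
    design = np.hstack([src, np.ones((n, 1))])
    if n >= 4 and np.linalg.matrix_rank(design) == 4:
        coef, *_ = np.linalg.lstsq(design, tgt, rcond=None)
        linear = coef[:3].T
        translation = coef[3]
    else:
        if n >= 4:
            warnings.warn(
                "bead geometry is degenerate (coplanar/collinear); "
                "falling back to translation-only registration"
            )
        linear = np.eye(3)
        translation = tgt.mean(axis=0) - src.mean(axis=0)
    transform = Transform3D(linear=linear, translation=translation)
    resid = transform.apply(src) - tgt
    transform.rms_residual = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return transform


def _preprocess(volume: VoxelVolume, smooth_sigma_um, background_quantile):
    """Background-subtract and smooth, anisotropy-aware."""
    data = volume.data.astype(float)
    background = np.quantile(data, background_quantile)
    data = (data - background).clip(min=0)
    dx, dy, dz = volume.voxel_size
    sigma_vox = (smooth_sigma_um / dz, smooth_sigma_um / dy, smooth_sigma_um / dx)
    return ndimage.gaussian_filter(data, sigma=sigma_vox)


def _watershed_on_distance(
    binary: np.ndarray,
    voxel_size,
    min_marker_distance_um: float,
) -> np.ndarray:
    """Marker-controlled watershed on the EDT of a binary foreground."""
    if not binary.any():
        return np.zeros(binary.shape, dtype=np.int32)
    dx, dy, dz = voxel_size
    distance = ndimage.distance_transform_edt(binary, sampling=(dz, dy, dx))
    min_dist_vox = max(int(min_marker_distance_um / max(dx, dy)), 1)
    peaks = peak_local_max(
        distance,
        labels=binary,
        min_distance=min_dist_vox,
        exclude_border=False,
    )
    markers = np.zeros(binary.shape, dtype=np.int32)
    for i, pk in enumerate(peaks, start=1):
        markers[tuple(pk)] = i
    if markers.max() == 0:
        lab, _ = ndimage.label(binary)
        return lab.astype(np.int32)
    labels = segmentation.watershed(-distance, markers=markers, mask=binary)
    return _relabel_consecutive(labels)


def _relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    vals = np.unique(labels)
    vals = vals[vals > 0]
    out = np.zeros_like(labels, dtype=np.int32)
    for i, v in enumerate(vals, start=1):
        out[labels == v] = i
    return out


def segment_nuclei(
    dapi: VoxelVolume,
    smooth_sigma_um: float = 0.3,
    background_quantile: float = 0.25,
    threshold: float | None = None,
    min_marker_distance_um: float = 2.0,
    min_voxels: int = 50,
) -> VoxelVolume:
    """Segment nuclei from a nuclear-stain volume.

    Background is subtracted (low-quantile offset), the signal smoothed
    with an anisotropy-aware Gaussian, binarized (Otsu unless a threshold
    is given), and foreground objects split by watershed on the distance
    transform.  Objects below ``min_voxels`` are removed.  Deterministic
    for fixed parameters.
    """
    smoothed = _preprocess(dapi, smooth_sigma_um, background_quantile)
    if smoothed.max() <= 0:
        return VoxelVolume(np.zeros(dapi.data.shape, np.int32), dapi.voxel_size)
    thr = filters.threshold_otsu(smoothed) if threshold is None else threshold
    binary = smoothed > thr
    binary = ndimage.binary_opening(binary, iterations=1)
    labels = _watershed_on_distance(binary, dapi.voxel_size, min_marker_distance_um)
    for region in measure.regionprops(labels):
        if region.num_pixels < min_voxels:
            labels[labels == region.label] = 0
    return VoxelVolume(_relabel_consecutive(labels), dapi.voxel_size)


def _sphericity(mask: np.ndarray, voxel_size) -> float:
    """pi^(1/3) (6V)^(2/3) / A with A from a marching-cubes surface mesh."""
    dx, dy, dz = voxel_size
    volume = mask.sum() * dx * dy * dz
    padded = np.pad(mask, 1).astype(float)
    try:
        verts, faces, *_ = measure.marching_cubes(padded, 0.5, spacing=(dz, dy, dx))
        area = measure.mesh_surface_area(verts, faces)
    except (ValueError, RuntimeError):
        return 0.0
    if area <= 0:
        return 0.0
    return float(np.pi ** (1 / 3) * (6 * volume) ** (2 / 3) / area)


def filter_interphase(
    labels: VoxelVolume,
    min_voxels: int = 100,
    max_voxels: int = 10**9,
    min_sphericity: float = 0.6,
    embryo_id: int = 0,
) -> tuple[VoxelVolume, list[NucleusRecord]]:
    """Keep interphase-like nuclei, by size and sphericity.

    Mitotic figures and debris are rejected on shape: a label is kept when
    its voxel count is within bounds and its sphericity (ratio of the
    equivalent sphere's surface to the measured mesh surface) exceeds the
    threshold.  Returns the filtered label volume (labels renumbered) and
    one :class:`NucleusRecord` per input label.
    """
    data = labels.data
    dx, dy, dz = labels.voxel_size
    records = []
    keep = np.zeros_like(data, dtype=np.int32)
    for region in measure.regionprops(data):
        vox = region.num_pixels
        vol_um3 = vox * dx * dy * dz
        diameter = (6.0 * vol_um3 / np.pi) ** (1.0 / 3.0)
        sph = _sphericity(data == region.label, labels.voxel_size)
        ok = min_voxels <= vox <= max_voxels and sph >= min_sphericity
        records.append(
            NucleusRecord(
                nucleus_id=int(region.label),
                embryo_id=embryo_id,
                voxel_count=int(vox),
                diameter_um=float(diameter),
                sphericity=sph,
                interphase=bool(ok),
            )
        )
        if ok:
            keep[data == region.label] = region.label
    return VoxelVolume(_relabel_consecutive(keep), labels.voxel_size), records


def segment_territories(
    territory_channel: VoxelVolume,
    nuclear_labels: VoxelVolume,
    smooth_sigma_um: float = 0.2,
    background_quantile: float = 0.25,
    threshold: float | None = None,
    min_marker_distance_um: float = 1.0,
    min_voxels: int = 20,
) -> VoxelVolume:
    """Segment chromosome territories inside the nuclear mask.

    Same recipe as nucleus segmentation, with signal outside nuclei zeroed
    by the nuclear mask before binarization, so territory labels never
    extend past their nucleus.  Returns a label volume; use
    ``nuclear_labels`` to look up each territory's nucleus.
    """
    nuc_mask = nuclear_labels.data > 0
    smoothed = _preprocess(territory_channel, smooth_sigma_um, background_quantile)
    smoothed[~nuc_mask] = 0.0
    if smoothed.max() <= 0:
        return VoxelVolume(
            np.zeros(territory_channel.data.shape, np.int32),
            territory_channel.voxel_size,
        )
    thr = filters.threshold_otsu(smoothed[nuc_mask]) if threshold is None else threshold
    binary = (smoothed > thr) & nuc_mask
    labels = _watershed_on_distance(
        binary, territory_channel.voxel_size, min_marker_distance_um
    )
    for region in measure.regionprops(labels):
        if region.num_pixels < min_voxels:
            labels[labels == region.label] = 0
    return VoxelVolume(_relabel_consecutive(labels), territory_channel.voxel_size)


#: Default developmental stage bins by nucleus count per embryo.
DEFAULT_STAGE_BINS = ((1, 4, "1-4"), (5, 16, "5-16"), (17, 24, "17-24"),
                      (25, 40, "25-40"))


def stage_embryo(
    nucleus_count: int,
    bins=DEFAULT_STAGE_BINS,
    merge_first: bool = False,
) -> str:
    """Assign a developmental stage bin from the embryo's nucleus count.

    With ``merge_first`` the smallest bin is folded into the next one
    (labelled ``"<=16"`` for the default bins), the merge applied when the
    earliest stages are too sparse for stage-wise statistics.  Counts above
    the last bin go to ``">40"``-style overflow; zero counts are
    ``"unstaged"``.
    """
    if nucleus_count <= 0:
        return "unstaged"
    bins = list(bins)
    if merge_first and len(bins) >= 2:
        lo0, _, _ = bins[0]
        _, hi1, label1 = bins[1]
        bins = [(lo0, hi1, f"<={hi1}")] + bins[2:]
    for lo, hi, label in bins:
        if lo <= nucleus_count <= hi:
            return label
    return f">{bins[-1][1]}"
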