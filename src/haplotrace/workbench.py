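"""Pipeline configuration and the end-to-end driver.

``run_pipeline`` chains the full analysis — segment nuclei, segment
territories, detect foci, trace, assign strains, apply drop-out criteria,
compute the mean-distance matrix and its power-law fit — on a rendered
scene (synthetic by default, so the whole pipeline can be exercised and
validated against exact ground truth).  Every numeric threshold lives in
:class:`PipelineConfig`; all randomness flows from its single seed, and
identical configurations reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as htio
from .conformation_stats import fit_power_law, mean_distance_matrix, \
    normalize_observed_expected
from .core import VoxelVolume
from .haplotyping import assign_strains, exclusion_accounting
from .image_prep import filter_interphase, segment_nuclei, segment_territories
from .polymer_sim import PolymerParams, SceneSpec, default_region_coords, \
    render_scene, simulate_traces
from .tracing import apply_dropout_criteria, detect_foci, trace_chromosomes

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Every tunable constant of the pipeline in one serializable place.

    The filter defaults are the pipeline's quality-control thresholds: at
    most 4 traces per nucleus and 2 per strain, at least 4 regions per
    trace, hybridization-quality thresholds of >6 regions per trace and
    >21 measurements per region pair for population matrices, a 5% marker
    overlap cutoff, and a 6 µm partner gap for homolog pairing.
    """

    # scene / polymer
    n_nuclei: int = 4
    step_size_um: float = 0.4
    scaling_exponent: float = 0.5
    n_regions: int = 21
    dropout_rate: float = 0.0
    overlap_fraction: float = 0.0
    voxel_size: tuple = (0.1, 0.1, 0.2)
    noise_sd: float = 0.0
    # segmentation
    foci_threshold: float = 100.0
    min_sphericity: float = 0.6
    # trace filters
    min_regions_per_trace: int = 4
    max_traces_per_nucleus: int = 4
    max_traces_per_strain: int = 2
    min_regions_stats: int = 7
    min_pair_count: int = 22
    marker_overlap_cutoff: float = 0.05
    partner_gap_um: float = 6.0
    # clustering
    cluster_resolution: float = 0.7
    cluster_excluded_regions: tuple = (17,)
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("voxel_size", "cluster_excluded_regions"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    """Bundle of everything the pipeline computed."""

    config: PipelineConfig
    traces: list
    ledger: object
    accounting: object
    mean_matrix: object
    fit: object
    normalized: np.ndarray
    truth: object
    provenance: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig, out_dir=None) -> PipelineResult:
    """Run the synthetic end-to-end pipeline under one configuration.

    Renders a scene from the configured polymer parameters, then runs
    segmentation, foci detection, tracing, strain assignment, drop-out
    accounting, and population statistics.  When ``out_dir`` is given,
    trace tables, the exclusion ledger, matrices and a provenance record
    (config hash + seed) are written there.
    """
    coords = default_region_coords(config.n_regions)
    params = PolymerParams(
        a=config.step_size_um,
        s=config.scaling_exponent,
        region_coords=coords,
        dropout_rate=config.dropout_rate,
        seed=config.seed,
    )
    spec = SceneSpec(
        n_nuclei=config.n_nuclei,
        overlap_fraction=config.overlap_fraction,
        voxel_size=config.voxel_size,
        noise_sd=config.noise_sd,
        seed=config.seed,
    )
    sim = simulate_traces(params, spec.n_nuclei * spec.traces_per_nucleus)
    scene = render_scene(spec, sim)

    nuclei = segment_nuclei(scene.dapi)
    nuclei, _ = filter_interphase(nuclei, min_sphericity=config.min_sphericity)
    territories = segment_territories(scene.territory, nuclei)

    foci = []
    for rid, channel in scene.spots.items():
        foci.extend(
            detect_foci(
                channel,
                region_id=rid,
                threshold=config.foci_threshold,
                territory_labels=territories,
                nucleus_labels=nuclei,
            )
        )
    region_ids = np.arange(1, config.n_regions + 1)
    traces = trace_chromosomes(foci, region_ids)

    strain_masks = {}
    for nid in np.unique(nuclei.data):
        if nid == 0:
            continue
        in_nucleus = nuclei.data == nid
        strain_masks[int(nid)] = {
            s: VoxelVolume(scene.markers[s].data & in_nucleus, config.voxel_size)
            for s in scene.markers
        }
    traces = assign_strains(traces, strain_masks)

    kept, ledger = apply_dropout_criteria(
        traces,
        min_regions=config.min_regions_per_trace,
        max_traces_per_nucleus=config.max_traces_per_nucleus,
        max_traces_per_strain=config.max_traces_per_strain,
    )
    accounting = exclusion_accounting(ledger)

    matrix = mean_distance_matrix(
        kept,
        coords,
        min_regions=config.min_regions_stats,
        min_pair_count=min(config.min_pair_count, max(len(kept), 1)),
    )
    try:
        fit = fit_power_law(matrix)
        normalized = normalize_observed_expected(matrix, fit)
    except ValueError:
        fit, normalized = None, np.full(matrix.mean.shape, np.nan)

    provenance = {"config_hash": config.config_hash, "seed": config.seed}
    result = PipelineResult(
        config=config,
        traces=kept,
        ledger=ledger,
        accounting=accounting,
        mean_matrix=matrix,
        fit=fit,
        normalized=normalized,
        truth=scene.truth_traces,
        provenance=provenance,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    htio.save_traces(out_dir / "traces.csv", result.traces)
    result.accounting.to_csv(out_dir / "exclusion_ledger.csv", index=False)
    htio.save_matrix(
        out_dir / "mean_distance_matrix.csv",
        result.mean_matrix.mean,
        result.mean_matrix.region_coords,
    )
    htio.save_matrix(out_dir / "normalized_matrix.csv", result.normalized)
    summary = dict(result.provenance)
    if result.fit is not None:
        summary["power_law"] = {
            "a_um": result.fit.a,
            "s": result.fit.s,
            "ci95_a": list(result.fit.ci95_a),
            "ci95_s": list(result.fit.ci95_s),
        }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
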