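import numpy as np
import pytest

from haplotrace.polymer_sim import (
    PolymerParams,
    SceneSpec,
    default_region_coords,
    render_scene,
    simulate_traces,
)


@pytest.fixture(scope="session")
def small_scene():
    """Two nuclei, eight regions, disjoint strain markers, no noise."""
    params = PolymerParams(
        a=0.35, s=0.5, region_coords=default_region_coords(8), seed=11
    )
    spec = SceneSpec(n_nuclei=2, overlap_fraction=0.0, seed=11)
    traces = simulate_traces(params, 4)
    return spec, render_scene(spec, traces)


@pytest.fixture(scope="session")
def rw_traces():
    """Random-walk polymer population, 21 regions, no dropout."""
    params = PolymerParams(a=1.0, s=0.5, seed=7)
    return simulate_traces(params, 400), default_region_coords(21)
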