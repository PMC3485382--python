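import numpy as np
import pytest

from lfoamp import BoldRun, SyntheticSpec, VolumeGrid, generate_cohort


@pytest.fixture
def small_grid() -> VolumeGrid:
    return VolumeGrid.default((12, 12, 10), (3.0, 3.0, 3.0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def sinusoid_run(
    grid: VolumeGrid,
    freq_hz: float,
    amplitude: float = 1.0,
    n: int = 200,
    tr_s: float = 2.0,
    phase: float = 0.3,
) -> BoldRun:
    """Noise-free run where every voxel carries one sinusoid."""
    t = np.arange(n) * tr_s
    series = amplitude * np.sin(2 * np.pi * freq_hz * t + phase)
    data = np.broadcast_to(series, (*grid.dims, n)).copy()
    return BoldRun(grid, data, tr_s)


@pytest.fixture(scope="session")
def tiny_cohort(tmp_path_factory):
    """A 3+3-subject cohort on disk (16x16x12 grid, 40 acquired volumes)."""
    out = tmp_path_factory.mktemp("cohort")
    spec = SyntheticSpec(
        n_per_group=3,
        grid=VolumeGrid.default((16, 16, 12)),
        n_volumes_acquired=40,
        seed=99,
    )
    manifest = generate_cohort(spec, out)
    return spec, manifest, out
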