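import numpy as np
import pytest

from texsurf import PhantomSpec, generate_phantom, segment
from texsurf.phantom import suggested_range


@pytest.fixture(scope="session")
def default_phantom():
    """The standard two-target phantom used by the end-to-end checks."""
    spec = PhantomSpec()
    volume, gt, seeds = generate_phantom(spec)
    return spec, volume, gt, seeds


@pytest.fixture(scope="session")
def small_phantom():
    """A quick single-target phantom for unit-level pipeline tests."""
    spec = PhantomSpec(shape=(24, 96, 96), n_targets=1)
    volume, gt, seeds = generate_phantom(spec)
    return spec, volume, gt, seeds


@pytest.fixture(scope="session")
def pipeline_runs(default_phantom):
    """Memoised full-pipeline runs on the default phantom, keyed by slice
    spacing, so the spacing sweep and the recovery checks share work."""
    spec, volume, gt, seeds = default_phantom
    cache: dict[int, object] = {}

    def run(spacing_m: int):
        if spacing_m not in cache:
            cache[spacing_m] = segment(
                volume, seeds, suggested_range(spec, spacing_m)
            )
        return cache[spacing_m]

    return run


@pytest.fixture(scope="session")
def big_slice_phantom():
    """A single wide target whose interior dwarfs the filter footprint;
    used for the per-slice seeding-quality checks."""
    spec = PhantomSpec(
        shape=(16, 288, 288),
        n_targets=1,
        target_geometry=[((8.0, 144.0, 144.0), (7.0, 120.0, 120.0))],
    )
    volume, gt, seeds = generate_phantom(spec)
    contour = next(s for s in seeds if s.slice_index == 8)
    return volume, gt, contour


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
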