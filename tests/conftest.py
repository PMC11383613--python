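"""Shared fixtures.

``tiny_*`` fixtures use a reduced phantom (300 vertices/hemisphere, short
runs) for fast unit tests.  The two heavy session fixtures implement the
study protocols the recovery claims are evaluated on:

* ``recovery_study`` — ten independently seeded default phantoms (2,000
  vertices/hemisphere, 4 runs of 410 retained frames) run end-to-end;
* ``blur_results`` — one deeply sampled phantom (62 runs, the discovery-
  subject condition) swept over blur-control thresholds on raw and
  smoothed data.
"""

from dataclasses import replace

import numpy as np
import pytest

from striomap import PhantomSpec, simulate_bundle
from striomap.geometry import VolumeModel
from striomap.pipeline import evaluate_subject, run_blur_study


def tiny_spec(**overrides) -> PhantomSpec:
    base = dict(
        n_vertices_per_hemi=300,
        n_runs=2,
        frames_per_run=132,
        frames_dropped=12,
        rng_seed=5,
    )
    base.update(overrides)
    return PhantomSpec(**base)


@pytest.fixture(scope="session")
def tiny_bundle():
    return simulate_bundle(tiny_spec())


@pytest.fixture(scope="session")
def tiny_surface(tiny_bundle):
    return tiny_bundle.surface


@pytest.fixture(scope="session")
def tiny_volume(tiny_bundle):
    return tiny_bundle.volume


@pytest.fixture(scope="session")
def tiny_truth(tiny_bundle):
    return tiny_bundle.truth


@pytest.fixture(scope="session")
def cube_volume():
    """Solid 17^3 grid at 2-mm voxels, mask everywhere: a boundary-free
    domain for checking the volume smoother against the analytic kernel."""
    shape = (17, 17, 17)
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    affine[:3, 3] = -16.0
    return VolumeModel(shape=shape, affine=affine, mask=np.ones(shape, dtype=bool))


@pytest.fixture(scope="session")
def recovery_study():
    spec = PhantomSpec()
    return [evaluate_subject(replace(spec, rng_seed=seed)) for seed in range(10)]


@pytest.fixture(scope="session")
def blur_results():
    return run_blur_study(PhantomSpec(n_runs=62, rng_seed=11))
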