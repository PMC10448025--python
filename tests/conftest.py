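"""Shared fixtures: conditions, crafted images, and desk-scale scenarios."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mrwindow as mw

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture()
def registry():
    return mw.ConditionRegistry()


@pytest.fixture()
def brain_t1(registry):
    return registry.intern("T1WI-SE", "brain")


def make_series(voxels, condition, series_id="S1", patient_id="P1"):
    return mw.MRSeries(
        series_id=series_id,
        patient_id=patient_id,
        condition=condition,
        voxels=np.asarray(voxels, dtype=float),
    )


@pytest.fixture()
def lognormal_series(brain_t1):
    """A generic positive-intensity image with a broad histogram."""
    rng = np.random.default_rng(42)
    return make_series(rng.lognormal(5.0, 0.6, size=20000), brain_t1)


#: Strictly increasing node set used to craft exact-landmark images.
EXACT_NODES = np.array([1.0, 5.0, 12.0, 22.0, 30.0, 42.0, 55.0, 70.0, 82.0, 91.0, 100.0])


def exact_landmark_voxels(nodes=EXACT_NODES):
    """101 sorted voxels whose IOI percentiles equal ``nodes`` exactly.

    With 101 points the linear percentile at integer p picks element p with
    no interpolation, so the landmark vector is exactly the interpolated
    node values.
    """
    return np.interp(np.arange(101, dtype=float), mw.LANDMARK_PERCENTILES, nodes)


@pytest.fixture()
def identity_series(brain_t1):
    """An image whose landmarks coincide with a [1, 100] standard scale."""
    return make_series(exact_landmark_voxels(), brain_t1)


@pytest.fixture()
def identity_scale(brain_t1):
    return mw.StandardScale(condition=brain_t1, nodes=EXACT_NODES.copy(), n_images=1)


def small_scenario(**overrides):
    """Default study scaled down for unit tests (fewer patients/voxels)."""
    sc = mw.SimulationScenario.default()
    sc.patients = 24
    for rec in sc.conditions:
        rec.n_voxels = 1500
    for key, val in overrides.items():
        setattr(sc, key, val)
    return sc


QUICK_SAMPLER = mw.SamplerSettings(chains=2, warmup=300, draws=500)


@pytest.fixture(scope="session")
def recovery_runs():
    """Full-pipeline runs on the default scenario over five seeds (shared)."""
    return {
        seed: mw.end_to_end_recovery(mw.SimulationScenario.default(), seed=seed)
        for seed in (1, 2, 3, 4, 5)
    }


@pytest.fixture(scope="session")
def default_recovery(recovery_runs):
    return recovery_runs[1]
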