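import datetime as dt

import numpy as np
import pytest

import interrai_mh as m


@pytest.fixture(scope="session")
def registry():
    return m.build_registry()


@pytest.fixture(scope="session")
def scale_defs(registry):
    return m.load_scale_defs(registry=registry)


@pytest.fixture(scope="session")
def cap_defs(registry, scale_defs):
    return m.load_cap_defs(registry=registry, scale_defs=scale_defs)


@pytest.fixture(scope="session")
def small_cohort(registry, scale_defs):
    return m.simulate_cohort(m.SimConfig(n_persons=1000, seed=11), registry, scale_defs)


def make_record(registry, instrument="MH", level="min", **kwargs):
    """A record with every registry item at its min or max code."""
    spec = registry[instrument]
    responses = {
        it.item_code: (it.max_code if level == "max" else it.min_code) for it in spec.items
    }
    defaults = dict(
        person_id="t0",
        instrument=instrument,
        reason="admission",
        date=dt.date(2017, 3, 1),
        responses=responses,
        covariates={"homeless": False},
    )
    defaults.update(kwargs)
    return m.AssessmentRecord(**defaults)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20170301)
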