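"""Shared fixtures: published point estimates, MTC fits and a base PSA.

The expensive objects (MTC posterior fits, the probabilistic base case)
are session-scoped and fitted once at reduced but sufficient sizes; unit
tests that only need a deterministic parameter set use ``point_draw`` /
``make_draw`` which bypass the sampler entirely with the published
posterior means.
"""

from __future__ import annotations

import numpy as np
import pytest

from ascea import evidence_synthesis as ev
from ascea import parameters, psa
from ascea.synthetic import default_life_table

#: published posterior means used for deterministic unit-test draws
EFFICACY_MEANS = {
    "basfi": {"etoricoxib": -17.87, "celecoxib200": -10.12,
              "celecoxib400": -11.80, "diclofenac": -11.51,
              "naproxen": -14.82},
    "basdai": {"etoricoxib": -28.53, "celecoxib200": -18.47,
               "celecoxib400": -21.77, "nsnsaid": -23.46},
    "disc": {"etoricoxib": 0.063, "celecoxib200": 0.225,
             "celecoxib400": 0.177, "nsnsaid": 0.149},
}

MTC_TEST_ITERATIONS = 10000
PSA_TEST_ITERATIONS = 2000


@pytest.fixture(scope="session")
def trial_arms():
    return ev.read_trials()


@pytest.fixture(scope="session")
def registry():
    return parameters.load_registry()


@pytest.fixture(scope="session")
def life_table():
    return default_life_table()


@pytest.fixture(scope="session")
def mtc_posteriors(trial_arms):
    """The three evidence-synthesis fits on the bundled trial table."""
    return {
        "basfi": ev.mtc_continuous(trial_arms, "basfi_cfb",
                                   iterations=MTC_TEST_ITERATIONS, seed=11),
        "basdai": ev.mtc_continuous(trial_arms, "basdai_cfb",
                                    iterations=MTC_TEST_ITERATIONS,
                                    seed=12),
        "disc": ev.mtc_binomial(trial_arms,
                                iterations=MTC_TEST_ITERATIONS, seed=13),
    }


@pytest.fixture(scope="session")
def mtc_draws(mtc_posteriors):
    return {k: p.absolute() for k, p in mtc_posteriors.items()}


@pytest.fixture(scope="session")
def base_psa(mtc_draws, registry, life_table):
    """Base-case probabilistic analysis shared across test modules."""
    return psa.run_psa("base", mtc_draws, registry, life_table=life_table,
                       iterations=PSA_TEST_ITERATIONS, seed=42)


def _point_efficacy():
    return {out: {t: np.array([v]) for t, v in vals.items()}
            for out, vals in EFFICACY_MEANS.items()}


@pytest.fixture(scope="session")
def point_draw(registry):
    """Deterministic n=1 draw at the published point estimates."""
    return parameters.sample_parameter_draw(
        registry, _point_efficacy(), n=1, rng=0, point_estimate=True)


@pytest.fixture
def make_draw(registry):
    """Factory for deterministic draws with per-parameter overrides.

    Overrides address the draw's group dicts, e.g.
    ``make_draw(safety={"pub_nsnsaid": 0.027}, n=1)``.
    """

    def _make(n: int = 1, **overrides):
        draw = parameters.sample_parameter_draw(
            registry, _point_efficacy(), n=n, rng=0, point_estimate=True)
        for group_name, entries in overrides.items():
            group = getattr(draw, group_name)
            for key, value in entries.items():
                group[key] = np.full(n, float(value))
        return draw

    return _make
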