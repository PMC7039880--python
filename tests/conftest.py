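"""Shared fixtures: small pools and reduced-scale scenario runs.

Scenario tables are session-scoped because several pattern analyses
(species-abundance tails, dissimilarity-overlap, ordination, effective
Lotka-Volterra variability) interrogate the same simulated campaigns.
"""

from __future__ import annotations

import numpy as np
import pytest

from micrm.sampling import (
    Environment,
    GlobalParameters,
    RegionalPool,
    ResourceSchema,
    emp_parameters,
    sample_pool,
)
from micrm.scenarios import run_hmp

# reduced scale used for the structured (host-associated) scenarios: the
# smallest scale at which the preferred-class consumption probability
# (1 + (M - M_A)/M_A q) mu_c / (M c1) stays below 1 for q = 0.9, mu_c = 10
HMP_TEST_SCALE = 0.2
HMP_TEST_SAMPLES_PER_SITE = 12


@pytest.fixture(scope="session")
def micro_pool() -> tuple[RegionalPool, Environment]:
    """Single species on a single resource, with closed-form equilibrium.

    With g = w = tau_R = 1, l = 0.8, c = 1, m = 0.1 and kappa = 200 the
    fixed point is R* = m / ((1-l) c) = 0.5 and
    N* = (kappa - R*/tau_R) / (c R* (1-l)) = 1995.
    """
    params = GlobalParameters(
        M=1, T=1, S_tot=1, F=1, S=1, mu_c=1.0, c0=0.0, c1=1.0, q=0.0,
        s=1.0, f_w=1.0, f_s=0.0, m_mean=0.1, m_sd=0.0, l=0.8,
        n_generalists=0,
    )
    schema = ResourceSchema.from_params(params)
    pool = RegionalPool(
        c=np.ones((1, 1)),
        D=np.ones((1, 1)),
        m_base=np.array([0.1]),
        family_of=np.array([0]),
        schema=schema,
        params=params,
        seed=0,
    )
    env = Environment(kappa=np.array([200.0]))
    return pool, env


@pytest.fixture(scope="session")
def small_emp_pool() -> RegionalPool:
    """Quarter-scale unstructured pool (45 species, 23 resources)."""
    return sample_pool(emp_parameters(scale=0.25, M=23), seed=11)


@pytest.fixture(scope="session")
def hmp_simple_table():
    """Reduced structured scenario, three sites, two single resources each."""
    return run_hmp(
        "distinct_simple",
        scale=HMP_TEST_SCALE,
        n_per_site=HMP_TEST_SAMPLES_PER_SITE,
        master_seed=101,
    )


@pytest.fixture(scope="session")
def hmp_no_taxonomy_table():
    """Same supply draws as the structured run but q = 0 (no families)."""
    return run_hmp(
        "no_taxonomy",
        scale=HMP_TEST_SCALE,
        n_per_site=HMP_TEST_SAMPLES_PER_SITE,
        master_seed=101,
    )


@pytest.fixture(scope="session")
def hmp_overlapping_table():
    """Metabolically overlapping variant: random resource subsets per site."""
    return run_hmp(
        "overlapping_complex",
        scale=HMP_TEST_SCALE,
        n_per_site=HMP_TEST_SAMPLES_PER_SITE,
        master_seed=101,
    )
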